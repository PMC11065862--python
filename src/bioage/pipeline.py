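"""Config-driven end-to-end runner.

Reproduces the full analysis table set — exclusion flow, weighted
descriptives, the Model-1/2/3 odds-ratio ladder, spline dose-response
curves, ROC/DCA, subgroup and sensitivity analyses — on either a synthetic
cohort or a delimited cohort file, writing delimited outputs plus a run
manifest with content hashes.

Column dictionary (the standard cohort table)
--------------------------------------------
id; stratum; psu; weight — survey design.
ca_years — chronological age.
sex (female/male); race_ethnicity (5 levels); education (3); marital (4);
pir; physical_activity (min/week); hei2015 (0-100); bmi (kg/m^2);
smoking (never/former/now); drinking (never/former/mild/moderate/heavy);
cvd_history (bool) — covariates.
sbp_reading_1..3, dbp_reading_1..3 (mmHg) or pre-averaged sbp_mmhg/dbp_mmhg.
dm_doctor_dx, dm_medication (bool); hba1c_pct; fasting_glucose_mmol_l;
ogtt_glucose_mmol_l; fasting_insulin_uu_ml — diabetes markers.
etdrs_grade_left/right — per-eye retinopathy severity (>= 14 shows lesions).
ln_crp_mg_dl; creatinine_umol_l; albumin_g_l; total_cholesterol_mmol_l;
urea_nitrogen_mmol_l; alk_phos_u_l; lymphocyte_pct; mcv_fl; rdw_pct;
wbc_1000_cells_ul — clock biomarkers not named above.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    KDM_BIOMARKERS,
    apply_exclusions,
    average_bp,
    derive_variables,
)
from .evaluation import compare_predictors
from .kdm import compute_ba, fit_kdm
from .phenoage import PHENOAGE_BIOMARKERS, compute_phenoage, compute_xb
from .rcs import fit_spline_curve
from .survey import (
    MODEL2_COVARIATES,
    MODEL3_EXTRA,
    SurveyDesign,
    domain_mean_ttest,
    model_suite,
    rao_scott_chi2,
    trend_test,
    weighted_mean_se,
    weighted_table,
)
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger("bioage.pipeline")

__all__ = ["RunConfig", "run_pipeline", "derive_cohort", "add_age_measures"]

VALID_EXPOSURES = ("ba_years", "pa_years", "ca_years", "ba_accel", "pa_accel")

DEFAULT_SUBGROUP_VARS = ("ca_group", "sex", "cvd_history", "hypertension", "smoking")

_REQUIRED_COLUMNS = (
    "stratum", "psu", "weight", "ca_years", "sex", "race_ethnicity",
    "education", "marital", "pir", "physical_activity", "hei2015", "bmi",
    "smoking", "drinking", "cvd_history", "etdrs_grade_left",
    "etdrs_grade_right",
) + KDM_BIOMARKERS


@dataclass
class RunConfig:
    """Everything one run needs; loadable from a YAML file."""

    mode: str = "synthetic"  # "synthetic" | "file"
    cohort_path: str | None = None
    column_map: Mapping[str, str] = field(default_factory=dict)
    simulation: Mapping = field(default_factory=dict)
    exposures: Sequence[str] = ("ba_years", "pa_years", "ca_years", "ba_accel", "pa_accel")
    subgroup_vars: Sequence[str] = DEFAULT_SUBGROUP_VARS
    dm_only_sensitivity: bool = True
    insulin_sensitivity: bool = True
    weighted_evaluation: bool = False
    kdm_survey_weighted: bool = False
    outdir: str = "bioage_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "file"):
            raise ValueError(f"mode must be 'synthetic' or 'file', got {self.mode!r}")
        if self.mode == "file" and not self.cohort_path:
            raise ValueError("mode 'file' requires cohort_path")
        bad = [e for e in self.exposures if e not in VALID_EXPOSURES]
        if bad:
            raise ValueError(f"unknown exposures {bad}; valid: {VALID_EXPOSURES}")


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.mode == "synthetic":
        sim = SimulationConfig(**config.simulation)
        df, truth = simulate_cohort(sim, seed=config.seed)
        df.attrs["ground_truth"] = truth
        return df
    sep = "\t" if str(config.cohort_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(config.cohort_path, sep=sep)
    if config.column_map:
        df = df.rename(columns=dict(config.column_map))
    return df


def _check_columns(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")


def derive_cohort(df: pd.DataFrame):
    """Derived variables + age restriction + exclusion cascade."""
    df = df.loc[df["ca_years"] >= 40].copy()
    if "sbp_mmhg" not in df.columns and "sbp_reading_1" in df.columns:
        reads = [c for c in df.columns if c.startswith("sbp_reading_")]
        pairs = df[[*reads, *(c.replace("sbp", "dbp") for c in reads)]].to_numpy()
        k = len(reads)
        avg = np.array([
            average_bp([(row[i], row[k + i]) for i in range(k) if not np.isnan(row[i])])
            for row in pairs
        ])
        df["sbp_mmhg"], df["dbp_mmhg"] = avg[:, 0], avg[:, 1]
    df = derive_variables(df)
    analytic, report = apply_exclusions(df)
    analytic = analytic.loc[analytic["dr"].notna()].copy()
    analytic["dr"] = analytic["dr"].astype(int)
    analytic["dm"] = analytic["dm"].astype(bool)
    return analytic, report


def add_age_measures(df: pd.DataFrame, survey_weighted_kdm: bool = False):
    """Train the KDM clock on the analytic sample and attach both age
    measures, acceleration flags and the categorical age group."""
    weights = df["weight"].to_numpy() if survey_weighted_kdm else None
    params = fit_kdm(df, KDM_BIOMARKERS, weights=weights)
    res = compute_ba(df, df["ca_years"].to_numpy(), params)
    df = df.copy()
    df["ba_years"] = res.ba
    df["ba_accel"] = np.asarray(res.ba) > df["ca_years"].to_numpy()
    pheno_inputs = {name: df[name].to_numpy() for name in PHENOAGE_BIOMARKERS
                    if name != "glucose_mmol_l"}
    pheno_inputs["glucose_mmol_l"] = df["fasting_glucose_mmol_l"].to_numpy()
    pheno_inputs["ca_years"] = df["ca_years"].to_numpy()
    df["pa_years"] = compute_phenoage(compute_xb(pheno_inputs))
    df["pa_accel"] = df["pa_years"] > df["ca_years"]
    df["ca_group"] = pd.Categorical(
        np.select(
            [df["ca_years"] < 60, df["ca_years"] < 70], ["<60", "60-69"], ">=70"
        ),
        categories=["<60", "60-69", ">=70"],
        ordered=True,
    )
    return df, params


_TABLE1_CONTINUOUS = ("ca_years", "pir", "physical_activity", "hei2015", "bmi",
                      "ba_years", "pa_years")
_TABLE1_CATEGORICAL = ("ca_group", "sex", "race_ethnicity", "marital", "education",
                       "smoking", "drinking", "cvd_history", "hypertension",
                       "ba_accel", "pa_accel")


def descriptive_table(df: pd.DataFrame, design: SurveyDesign, by: str = "dr") -> pd.DataFrame:
    """Weighted descriptives split by outcome, with design-based p-values."""
    rows = []
    flag = df[by].astype(bool).to_numpy()
    for var in _TABLE1_CONTINUOUS:
        if var not in df.columns:
            continue
        x = df[var].to_numpy(dtype=float)
        m, se = weighted_mean_se(x, design)
        m1, se1 = weighted_mean_se(x[flag], design.subset(flag))
        m0, se0 = weighted_mean_se(x[~flag], design.subset(~flag))
        p = domain_mean_ttest(x, flag, design)["p"]
        rows.append({"variable": var, "level": "", "kind": "continuous",
                     "overall": f"{m:.2f} ({se:.2f})",
                     "without": f"{m0:.2f} ({se0:.2f})",
                     "with": f"{m1:.2f} ({se1:.2f})", "p": p})
    for var in _TABLE1_CATEGORICAL:
        if var not in df.columns:
            continue
        try:
            _, p = rao_scott_chi2(df[var].astype(str), flag, design)
        except ValueError:
            p = np.nan
        tab_all = weighted_table(df[var].astype(str), design)
        tab1 = weighted_table(df.loc[flag, var].astype(str), design.subset(flag))
        tab0 = weighted_table(df.loc[~flag, var].astype(str), design.subset(~flag))
        for lv in tab_all.index:
            fmt = lambda t: (f"{int(t.loc[lv, 'n'])} ({t.loc[lv, 'weighted_pct']:.2f})"
                             if lv in t.index else "0 (0.00)")
            rows.append({"variable": var, "level": lv, "kind": "categorical",
                         "overall": fmt(tab_all), "without": fmt(tab0),
                         "with": fmt(tab1), "p": p})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns {artifact name: path}.

    Fails fast on an invalid config; a failure in a later stage is logged,
    earlier outputs are kept, and the exception propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, fname: str):
        path = outdir / fname
        frame.to_csv(path, index=False)
        artifacts[name] = path
        log.info("wrote %s (%d rows)", path, len(frame))

    raw = _load_cohort(config)
    _check_columns(raw)
    analytic, report = derive_cohort(raw)
    emit("exclusion_flow", report.to_frame(), "exclusion_flow.csv")

    analytic, kdm_params = add_age_measures(analytic, config.kdm_survey_weighted)
    kdm_path = outdir / "kdm_params.tsv"
    kdm_params.save(kdm_path)
    artifacts["kdm_params"] = kdm_path
    design = SurveyDesign.from_frame(analytic)

    emit("table1", descriptive_table(analytic, design), "table1.csv")

    # Model 1-3 ladder per exposure, plus the grouped-CA trend test
    tables = []
    for exposure in config.exposures:
        tables.append(model_suite(analytic, design, exposure))
    t2 = pd.concat(tables, ignore_index=True)
    grouped = model_suite(analytic, design, "ca_group")
    grouped["exposure"] = "ca_group"
    trend_rows = []
    for model in (1, 2, 3):
        covs = [c for c in (MODEL2_COVARIATES if model > 1 else [])
                if c != "ca_years"] + (MODEL3_EXTRA if model == 3 else [])
        p = trend_test(analytic, "dr", "ca_group", design, covs)
        trend_rows.append({"model": model, "exposure": "ca_group",
                           "term": "trend", "p": p})
    t2 = pd.concat([t2, grouped, pd.DataFrame(trend_rows)], ignore_index=True)
    emit("table2", t2, "table2.csv")

    for exposure in ("ba_years", "pa_years", "ca_years"):
        if exposure not in config.exposures:
            continue
        covs = [c for c in MODEL2_COVARIATES + MODEL3_EXTRA
                if c != exposure and not (exposure == "ca_years" and c == "ca_years")]
        sc = fit_spline_curve(analytic, exposure, "dr", covs, design)
        frame = sc.curve.assign(p_nonlinearity=sc.p_nonlinearity,
                                reference=sc.reference)
        emit(f"spline_{exposure}", frame, f"spline_{exposure}.csv")

    cont = [e for e in config.exposures if e in ("ba_years", "pa_years", "ca_years")]
    if cont:
        results = compare_predictors(
            analytic, design, exposures=cont, weighted=config.weighted_evaluation
        )
        auc_rows = []
        for exp_col, res in results.items():
            emit(f"roc_{exp_col}", res["roc"].to_frame(), f"roc_{exp_col}.csv")
            emit(f"dca_{exp_col}", res["dca"].to_frame(), f"dca_{exp_col}.csv")
            auc_rows.append({"exposure": exp_col, "auc": res["roc"].auc})
        emit("auc", pd.DataFrame(auc_rows), "auc.csv")

    sub_tables = []
    from .survey import subgroup_analysis
    for exposure in ("ba_years", "pa_years", "ca_years"):
        if exposure not in config.exposures:
            continue
        sub = subgroup_analysis(analytic, design, exposure,
                                [v for v in config.subgroup_vars if v != exposure])
        sub_tables.append(sub)
    if sub_tables:
        emit("subgroups", pd.concat(sub_tables, ignore_index=True), "subgroups.csv")

    if config.dm_only_sensitivity:
        dm_mask = analytic["dm"].to_numpy()
        dm_df = analytic.loc[dm_mask]
        dm_design = design.subset(dm_mask)
        sens = pd.concat(
            [model_suite(dm_df, dm_design, e) for e in cont], ignore_index=True
        )
        emit("sensitivity_dm_only", sens, "sensitivity_dm_only.csv")
        if config.insulin_sensitivity and "homa_ir" in dm_df.columns:
            sens2 = pd.concat(
                [model_suite(dm_df, dm_design, e,
                             extra_covariates=("fasting_insulin_uu_ml", "homa_ir"))
                 for e in cont],
                ignore_index=True,
            )
            emit("sensitivity_insulin", sens2, "sensitivity_insulin.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "n_analytic": int(len(analytic)),
        "n_dr": int(analytic["dr"].sum()),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in artifacts.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return {k: str(v) for k, v in artifacts.items()}
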