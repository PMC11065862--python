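"""Synthetic NHANES-like cohorts with a known latent aging process.

The generator exists so that every downstream stage — clock training,
cohort derivation, design-based regression, splines, ROC/DCA — can be
exercised against known ground truth without any data download.

Structure of the simulation:

* Each subject has chronological age ``CA ~ Uniform(ca_range)`` and a latent
  biological age ``B = CA + Delta`` with ``Delta ~ Normal(0, latent_sd^2)``
  independent of CA.  ``Delta`` is the quantity the aging clocks are meant to
  pick up over and above CA.
* Every clock biomarker is a noisy linear function of B (log-CRP is
  simulated directly on the log scale), matching the linear-regression
  structure the Klemera-Doubal estimator assumes.
* A stratified design with ``n_strata`` strata and ``psus_per_stratum`` PSUs
  per stratum is laid over the sample; positive per-record weights follow
  the configured law and are scaled to sum to ``population_size``.  Weights
  are independent of the outcome (ignorable) unless the stress-test flag is
  set.
* Diabetes arises from a latent metabolic subpopulation whose glucose and
  HbA1c are shifted upward; DM status is then *classified* from the
  simulated labs and self-report via the same rules the cohort module
  applies to real data.
* Retinopathy occurs only among DM subjects, with log-odds linear in B
  (slope ``beta_latent``), optionally in CA directly, and in configured
  covariates.  Eye grades are emitted accordingly, with configurable
  missingness to exercise the exclusion cascade.

A single seed feeds a fixed set of named substreams (one per generation
stage), so adding a stage never perturbs draws of earlier stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import DR_MIN_GRADE, classify_dm_frame, classify_dr_frame

__all__ = [
    "BiomarkerLoading",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "designed_or",
    "DEFAULT_LOADINGS",
]


@dataclass(frozen=True)
class BiomarkerLoading:
    """Linear loading of one biomarker on latent biological age.

    ``value = intercept + slope * B + Normal(0, noise_sd^2)`` in the
    biomarker's native units.
    """

    intercept: float
    slope: float
    noise_sd: float


#: Default biomarker loadings: slopes and scatter chosen to resemble adult
#: cross-sectional trends in a general US population (units per year of
#: latent age).  Intercepts are extrapolations to age 0 of typical values at
#: age 60.
DEFAULT_LOADINGS: Mapping[str, BiomarkerLoading] = {
    "ln_crp_mg_dl": BiomarkerLoading(-2.50, 0.015, 1.00),
    "creatinine_umol_l": BiomarkerLoading(60.0, 0.30, 12.0),
    "hba1c_pct": BiomarkerLoading(4.70, 0.012, 0.35),
    "albumin_g_l": BiomarkerLoading(51.8, -0.08, 2.5),
    "total_cholesterol_mmol_l": BiomarkerLoading(4.40, 0.012, 1.00),
    "urea_nitrogen_mmol_l": BiomarkerLoading(2.30, 0.045, 1.40),
    "alk_phos_u_l": BiomarkerLoading(50.0, 0.25, 18.0),
    "sbp_mmhg": BiomarkerLoading(96.0, 0.55, 13.0),
    "fasting_glucose_mmol_l": BiomarkerLoading(4.40, 0.020, 0.70),
    "lymphocyte_pct": BiomarkerLoading(36.0, -0.10, 7.0),
    "mcv_fl": BiomarkerLoading(85.6, 0.06, 4.5),
    "rdw_pct": BiomarkerLoading(11.8, 0.025, 0.90),
    "wbc_1000_cells_ul": BiomarkerLoading(6.32, 0.012, 1.60),
}

_STAGES = (
    "design", "covariates", "latent", "biomarkers", "dm", "dr", "missingness",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator (defaults are the study
    conditions used throughout the test-bench)."""

    n_subjects: int = 2000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_law: Mapping[str, float] = field(
        default_factory=lambda: {"kind": "lognormal", "sigma": 0.5}
    )
    population_size: float = 1.0e6
    ca_range: tuple[float, float] = (40.0, 85.0)
    latent_sd: float = 9.0
    biomarker_loadings: Mapping[str, BiomarkerLoading] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    #: log-odds of DR per year of latent biological age (among DM)
    beta_latent: float = float(np.log(1.11))
    #: log-odds of DR per year of CA given latent age
    beta_ca_direct: float = 0.0
    #: additional DR log-odds, keyed "column=value"
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex=male": 0.3}
    )
    #: DR log-odds at latent age 60 with reference covariates (among DM);
    #: default calibrated so that roughly 27% of DM subjects (about 5% of the
    #: cohort) have DR, the prevalence pattern of the study population
    dr_intercept: float = -2.7
    #: metabolic-subpopulation membership: logit-linear in latent age,
    #: calibrated to about one in five subjects with DM
    dm_intercept: float = -1.8
    dm_slope: float = 0.04
    #: upward shifts applied to the metabolic subpopulation's labs
    dm_glucose_shift_mean: float = 4.8
    dm_hba1c_per_glucose: float = 0.45
    #: fractions exercising the exclusion cascade
    missing_both_eyes: float = 0.0
    missing_one_eye: float = 0.0
    missing_demographics: float = 0.0
    missing_covariates: float = 0.0
    #: stress-test flag: make weights depend on the latent deviation
    weights_outcome_correlated: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_strata < 1:
            raise ValueError("n_strata must be positive")
        if self.psus_per_stratum < 2:
            raise ValueError("psus_per_stratum must be >= 2 for variance estimation")
        if self.ca_range[1] <= self.ca_range[0]:
            raise ValueError("ca_range must be an increasing (min, max) pair")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be non-negative")
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        for name, ld in self.biomarker_loadings.items():
            if ld.noise_sd < 0:
                raise ValueError(f"biomarker_loadings[{name!r}].noise_sd must be >= 0")
        kind = self.weight_law.get("kind")
        if kind not in ("lognormal", "constant"):
            raise ValueError(f"weight_law.kind must be 'lognormal' or 'constant', got {kind!r}")
        for frac in ("missing_both_eyes", "missing_one_eye",
                     "missing_demographics", "missing_covariates"):
            v = getattr(self, frac)
            if not 0 <= v < 1:
                raise ValueError(f"{frac} must be in [0, 1)")


@dataclass(eq=False)
class GroundTruth:
    """What the generator knows and an analyst must estimate."""

    latent: pd.DataFrame  # id, ca_years, delta_years, latent_age_years
    designed_or_latent: float
    designed_or_ca_direct: float
    designed_covariate_ors: Mapping[str, float]


def designed_or(config: SimulationConfig) -> float:
    """The odds ratio per year of latent biological age built into the DR model."""
    return float(np.exp(config.beta_latent))


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort table plus its ground truth.

    ``seed`` overrides ``config.seed`` when given.  Deterministic: the same
    (config, seed) pair always yields identical tables.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = _substreams(cfg.seed)
    n = cfg.n_subjects

    # --- design: balanced random assignment of subjects to stratum/PSU cells
    cells = np.array(
        [(h, c) for h in range(1, cfg.n_strata + 1)
         for c in range(1, cfg.psus_per_stratum + 1)]
    )
    idx = np.tile(np.arange(len(cells)), n // len(cells) + 1)[:n]
    rng["design"].shuffle(idx)
    stratum = cells[idx, 0]
    psu = cells[idx, 1]
    if cfg.weight_law["kind"] == "lognormal":
        w = np.exp(rng["design"].normal(0.0, cfg.weight_law.get("sigma", 0.5), n))
    else:
        w = np.ones(n)

    # --- covariates
    rc = rng["covariates"]
    sex = np.where(rc.random(n) < 0.5, "female", "male")
    race = rc.choice(
        ["mexican_american", "non_hispanic_white", "non_hispanic_black",
         "other_hispanic", "other"],
        size=n, p=[0.12, 0.55, 0.18, 0.08, 0.07],
    )
    education = rc.choice(
        ["less_than_hs", "hs_or_equivalent", "above_hs"], size=n, p=[0.23, 0.25, 0.52]
    )
    marital = rc.choice(
        ["married", "never_married", "living_with_partner", "other"],
        size=n, p=[0.64, 0.07, 0.04, 0.25],
    )
    pir = np.clip(rc.normal(3.0, 1.6, n), 0.0, 5.0)
    physical_activity = np.exp(rc.normal(np.log(400.0), 1.0, n))
    hei2015 = np.clip(rc.normal(55.0, 12.0, n), 0.0, 100.0)
    bmi = np.clip(rc.normal(28.7, 5.5, n), 15.0, 60.0)
    smoking = rc.choice(["never", "former", "now"], size=n, p=[0.47, 0.33, 0.20])
    drinking = rc.choice(
        ["never", "former", "mild", "moderate", "heavy"],
        size=n, p=[0.10, 0.20, 0.42, 0.15, 0.13],
    )
    cvd_history = rc.random(n) < 0.10

    # --- latent aging
    rl = rng["latent"]
    ca = rl.uniform(*cfg.ca_range, n)
    delta = rl.normal(0.0, cfg.latent_sd, n) if cfg.latent_sd > 0 else np.zeros(n)
    latent = ca + delta
    if cfg.weights_outcome_correlated and cfg.latent_sd > 0:
        w = w * np.exp(0.2 * delta / cfg.latent_sd)
    w = w * (cfg.population_size / w.sum())

    # --- biomarkers: noisy linear functions of latent age
    rb = rng["biomarkers"]
    bio = {}
    for name, ld in cfg.biomarker_loadings.items():
        noise = rb.normal(0.0, ld.noise_sd, n) if ld.noise_sd > 0 else 0.0
        bio[name] = ld.intercept + ld.slope * latent + noise
    bio["lymphocyte_pct"] = np.clip(bio["lymphocyte_pct"], 1.0, 99.0)
    bio["fasting_glucose_mmol_l"] = np.clip(bio["fasting_glucose_mmol_l"], 2.5, None)

    # blood-pressure readings around the true SBP; diastolic loosely coupled
    sbp_true = bio.pop("sbp_mmhg")
    read_noise = 3.0 if cfg.biomarker_loadings["sbp_mmhg"].noise_sd > 0 else 0.0
    sbp_reads = sbp_true[:, None] + (
        rb.normal(0.0, read_noise, (n, 3)) if read_noise else np.zeros((n, 3))
    )
    dbp_true = 60.0 + 0.12 * (sbp_true - 96.0) + (
        rb.normal(0.0, 6.0, n) if read_noise else 0.0
    )
    dbp_reads = dbp_true[:, None] + (
        rb.normal(0.0, 2.0, (n, 3)) if read_noise else np.zeros((n, 3))
    )
    # averaging rule: first reading dropped (no zero diastolics generated)
    sbp_avg = sbp_reads[:, 1:].mean(axis=1)
    dbp_avg = np.clip(dbp_reads[:, 1:].mean(axis=1), 1.0, None)

    # --- diabetes: metabolic subpopulation with shifted labs
    rd = rng["dm"]
    p_metab = _expit(cfg.dm_intercept + cfg.dm_slope * (latent - 60.0))
    metab = rd.random(n) < p_metab
    glucose_shift = np.where(metab, rd.gamma(2.0, cfg.dm_glucose_shift_mean / 2.0, n), 0.0)
    fg = bio["fasting_glucose_mmol_l"] + glucose_shift
    hba1c = bio["hba1c_pct"] + cfg.dm_hba1c_per_glucose * glucose_shift
    ogtt = 1.25 * fg + 1.2 + (rd.normal(0.0, 1.0, n) if cfg.latent_sd > 0 else 0.0)
    dm_doctor_dx = metab & (rd.random(n) < 0.65)
    dm_medication = dm_doctor_dx & (rd.random(n) < 0.75)
    fasting_insulin = np.exp(rd.normal(np.log(10.0), 0.5, n)) * np.where(metab, 1.6, 1.0)

    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "stratum": stratum,
        "psu": psu,
        "weight": w,
        "ca_years": ca,
        "sex": sex,
        "race_ethnicity": race,
        "education": education,
        "marital": marital,
        "pir": pir,
        "physical_activity": physical_activity,
        "hei2015": hei2015,
        "bmi": bmi,
        "smoking": smoking,
        "drinking": drinking,
        "cvd_history": cvd_history,
        "sbp_reading_1": sbp_reads[:, 0],
        "sbp_reading_2": sbp_reads[:, 1],
        "sbp_reading_3": sbp_reads[:, 2],
        "dbp_reading_1": dbp_reads[:, 0],
        "dbp_reading_2": dbp_reads[:, 1],
        "dbp_reading_3": dbp_reads[:, 2],
        "sbp_mmhg": sbp_avg,
        "dbp_mmhg": dbp_avg,
        "fasting_glucose_mmol_l": fg,
        "ogtt_glucose_mmol_l": ogtt,
        "hba1c_pct": hba1c,
        "dm_doctor_dx": dm_doctor_dx,
        "dm_medication": dm_medication,
        "fasting_insulin_uu_ml": fasting_insulin,
        "ln_crp_mg_dl": bio["ln_crp_mg_dl"],
        "creatinine_umol_l": bio["creatinine_umol_l"],
        "albumin_g_l": bio["albumin_g_l"],
        "total_cholesterol_mmol_l": bio["total_cholesterol_mmol_l"],
        "urea_nitrogen_mmol_l": bio["urea_nitrogen_mmol_l"],
        "alk_phos_u_l": bio["alk_phos_u_l"],
        "lymphocyte_pct": bio["lymphocyte_pct"],
        "mcv_fl": bio["mcv_fl"],
        "rdw_pct": bio["rdw_pct"],
        "wbc_1000_cells_ul": bio["wbc_1000_cells_ul"],
    })

    # DM by the same classification rules applied to real cohorts
    dm = classify_dm_frame(df).astype(bool)

    # --- retinopathy among DM subjects
    rr = rng["dr"]
    lp = (
        cfg.dr_intercept
        + cfg.beta_latent * (latent - 60.0)
        + cfg.beta_ca_direct * (ca - 60.0)
    )
    for key, eff in cfg.covariate_effects.items():
        colname, _, lv = key.partition("=")
        colvals = df[colname]
        if colvals.dtype == bool:
            match = colvals == (lv in ("True", "true", "1"))
        else:
            match = colvals.astype(str) == lv
        lp = lp + eff * match.to_numpy(dtype=float)
    dr = dm.to_numpy() & (rr.random(n) < _expit(lp))

    # eye grades: worse-eye level by severity among DR, lesion-free otherwise
    worse = np.where(
        dr, rr.choice([14, 20, 31, 43], size=n, p=[0.30, 0.40, 0.20, 0.10]), 10
    )
    other = np.where(dr & (rr.random(n) < 0.5), 10, worse)
    left_first = rr.random(n) < 0.5
    df["etdrs_grade_left"] = np.where(left_first, worse, other).astype(float)
    df["etdrs_grade_right"] = np.where(left_first, other, worse).astype(float)

    df["dm"] = dm
    df["dr"] = dr.astype(int)

    # --- missingness (exclusion-cascade exercise); applied last so earlier
    # draws are untouched when the rates are zero
    rm = rng["missingness"]
    if cfg.missing_both_eyes > 0:
        hit = rm.random(n) < cfg.missing_both_eyes
        df.loc[hit, ["etdrs_grade_left", "etdrs_grade_right"]] = np.nan
        df.loc[hit, "dr"] = np.nan
    if cfg.missing_one_eye > 0:
        hit = rm.random(n) < cfg.missing_one_eye
        side = np.where(rm.random(n) < 0.5, "etdrs_grade_left", "etdrs_grade_right")
        for eye in ("etdrs_grade_left", "etdrs_grade_right"):
            df.loc[hit & (side == eye), eye] = np.nan
    if cfg.missing_demographics > 0:
        hit = rm.random(n) < cfg.missing_demographics
        df.loc[hit, "pir"] = np.nan
    if cfg.missing_covariates > 0:
        hit = rm.random(n) < cfg.missing_covariates
        df.loc[hit, "bmi"] = np.nan

    truth = GroundTruth(
        latent=pd.DataFrame({
            "id": df["id"],
            "ca_years": ca,
            "delta_years": delta,
            "latent_age_years": latent,
        }),
        designed_or_latent=designed_or(cfg),
        designed_or_ca_direct=float(np.exp(cfg.beta_ca_direct)),
        designed_covariate_ors={
            k: float(np.exp(v)) for k, v in cfg.covariate_effects.items()
        },
    )
    return df, truth


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
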