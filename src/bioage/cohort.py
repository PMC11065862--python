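"""Analysis-variable derivation and the exclusion cascade.

Turns raw participant records into the analytic cohort: diabetes (DM) from
laboratory thresholds and self-report, diabetic retinopathy (DR) from per-eye
retinopathy grades among DM participants, averaged blood pressure and
hypertension, HOMA-IR, smoking/drinking categories and BMI, then a sequential
exclusion cascade with per-step accounting.

Boundary semantics follow the written definitions literally: HbA1c strictly
*exceeding* 6.5 %, fasting glucose >= 7.0 mmol/L, random / 2-h OGTT glucose
>= 11.1 mmol/L, hypertension at SBP >= 140 or DBP >= 90 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phenoage import PHENOAGE_BIOMARKERS

__all__ = [
    "DR_MIN_GRADE",
    "KDM_BIOMARKERS",
    "ExclusionReport",
    "classify_dm",
    "classify_dr",
    "average_bp",
    "classify_hypertension",
    "homa_ir",
    "classify_drinking",
    "classify_smoking",
    "compute_bmi",
    "derive_variables",
    "apply_exclusions",
]

#: Lowest retinopathy severity level counting as DR: at least one
#: microaneurysm or blot hemorrhage (with or without severer lesions).
#: Grades follow a modified Airlie House ordering where 10 = no retinopathy
#: and levels >= 14 show definite lesions.
DR_MIN_GRADE = 14

#: The 8 KDM-clock biomarkers as cohort-table column names.
KDM_BIOMARKERS = (
    "ln_crp_mg_dl",
    "creatinine_umol_l",
    "hba1c_pct",
    "albumin_g_l",
    "total_cholesterol_mmol_l",
    "urea_nitrogen_mmol_l",
    "alk_phos_u_l",
    "sbp_mmhg",
)

# DM thresholds (units: %, mmol/L)
DM_HBA1C_EXCLUSIVE = 6.5
DM_FASTING_GLUCOSE = 7.0
DM_RANDOM_OGTT_GLUCOSE = 11.1


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or (pd.isna(v) if np.isscalar(v) else False)


def classify_dm(record) -> bool:
    """Diabetes from self-report, labs or medication.

    True iff a doctor's diagnosis, HbA1c strictly above 6.5 %, fasting
    glucose >= 7.0 mmol/L, random or 2-h OGTT glucose >= 11.1 mmol/L, or DM
    medication / insulin use.  ``record`` is any mapping (a table row); the
    random-glucose and OGTT criteria accept either of the columns
    ``random_glucose_mmol_l`` / ``ogtt_glucose_mmol_l``.  Raises if every
    marker is missing (such records are excluded upstream).
    """
    checks = [
        ("dm_doctor_dx", lambda v: bool(v)),
        ("hba1c_pct", lambda v: v > DM_HBA1C_EXCLUSIVE),
        ("fasting_glucose_mmol_l", lambda v: v >= DM_FASTING_GLUCOSE),
        ("random_glucose_mmol_l", lambda v: v >= DM_RANDOM_OGTT_GLUCOSE),
        ("ogtt_glucose_mmol_l", lambda v: v >= DM_RANDOM_OGTT_GLUCOSE),
        ("dm_medication", lambda v: bool(v)),
    ]
    any_seen = False
    result = False
    for key, rule in checks:
        v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
        if v is None or _is_missing(v):
            continue
        any_seen = True
        if rule(v):
            result = True
    if not any_seen:
        raise ValueError("all DM markers missing; record should be excluded upstream")
    return result


def classify_dr(record, is_dm: bool) -> bool:
    """Diabetic retinopathy at person level.

    Always False for non-DM participants.  Among DM participants the
    person-level grade is the worse eye; an ungradable eye takes the other
    eye's grade (so a single gradable eye decides).  True iff the person
    grade is at least :data:`DR_MIN_GRADE`.  Raises when both eyes are
    ungradable for a DM participant.
    """
    if not is_dm:
        return False
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k, None)
    left, right = get("etdrs_grade_left"), get("etdrs_grade_right")
    left_ok, right_ok = not _is_missing(left), not _is_missing(right)
    if not (left_ok or right_ok):
        raise ValueError("both eyes ungradable; record should be excluded upstream")
    if not left_ok:
        left = right
    if not right_ok:
        right = left
    return max(left, right) >= DR_MIN_GRADE


def average_bp(readings: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Average of repeated (systolic, diastolic) readings.

    A single reading is its own average.  With several, the first reading is
    dropped, then zero-diastolic readings are dropped from the remainder
    unless every remaining diastolic is zero (in which case the remainder is
    averaged as-is).  Applied in that order; the result is invariant to the
    order of readings 2..k.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("need at least one blood-pressure reading")
    for s, d in readings:
        if s < 0 or d < 0:
            raise ValueError("blood-pressure readings must be non-negative")
    if len(readings) == 1:
        return float(readings[0][0]), float(readings[0][1])
    rest = readings[1:]
    nonzero = [r for r in rest if r[1] > 0]
    use = nonzero if nonzero else rest
    sbp = float(np.mean([r[0] for r in use]))
    dbp = float(np.mean([r[1] for r in use]))
    return sbp, dbp


def classify_hypertension(sbp: float, dbp: float) -> bool:
    """SBP >= 140 mmHg or DBP >= 90 mmHg (both inclusive)."""
    if sbp < 0 or dbp < 0:
        raise ValueError("blood pressures must be non-negative")
    return sbp >= 140.0 or dbp >= 90.0


def homa_ir(fasting_glucose_mmol_l: float, fasting_insulin_uu_ml: float) -> float:
    """Insulin-resistance index: glucose (mmol/L) x insulin (uU/mL) / 22.5."""
    if fasting_glucose_mmol_l < 0 or fasting_insulin_uu_ml < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return fasting_glucose_mmol_l * fasting_insulin_uu_ml / 22.5


def classify_drinking(
    lifetime_drinks: float,
    past_year_drinks: float,
    drinks_per_day: float,
    sex: str,
) -> str:
    """Five-level drinking status.

    never: under 12 drinks in the lifetime.  former: at least 12 lifetime but
    none in the past year.  Otherwise per-day consumption in the last 12
    months, with sex-specific cutoffs: heavy at >= 3 (female) / >= 4 (male)
    drinks per day, mild at <= 1 (female) / <= 2 (male), moderate between.
    """
    if min(lifetime_drinks, past_year_drinks, drinks_per_day) < 0:
        raise ValueError("drink counts must be non-negative")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if lifetime_drinks < 12:
        return "never"
    if past_year_drinks == 0:
        return "former"
    heavy_cut = 3 if sex == "female" else 4
    mild_cut = 1 if sex == "female" else 2
    if drinks_per_day >= heavy_cut:
        return "heavy"
    if drinks_per_day <= mild_cut:
        return "mild"
    return "moderate"


def classify_smoking(lifetime_cigs: float, currently_smoking: bool) -> str:
    """never (<100 lifetime cigarettes), former (>=100 & quit), now."""
    if lifetime_cigs < 0:
        raise ValueError("lifetime cigarettes must be non-negative")
    if lifetime_cigs < 100:
        return "never"
    return "now" if currently_smoking else "former"


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, kg/m^2."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


# ---------------------------------------------------------------------------
# table-level derivation


def classify_dm_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_dm` over a cohort table.

    Missing markers are ignored; a row with every marker missing yields NA.
    """
    n = len(df)
    col = lambda name: df[name] if name in df.columns else pd.Series([np.nan] * n, index=df.index)
    marker_hits = [
        col("dm_doctor_dx").map(lambda v: bool(v), na_action="ignore"),
        col("hba1c_pct") > DM_HBA1C_EXCLUSIVE,
        col("fasting_glucose_mmol_l") >= DM_FASTING_GLUCOSE,
        col("random_glucose_mmol_l") >= DM_RANDOM_OGTT_GLUCOSE,
        col("ogtt_glucose_mmol_l") >= DM_RANDOM_OGTT_GLUCOSE,
        col("dm_medication").map(lambda v: bool(v), na_action="ignore"),
    ]
    markers = [
        "dm_doctor_dx", "hba1c_pct", "fasting_glucose_mmol_l",
        "random_glucose_mmol_l", "ogtt_glucose_mmol_l", "dm_medication",
    ]
    any_seen = pd.concat([col(m).notna() for m in markers], axis=1).any(axis=1)
    hit = pd.concat(
        [pd.Series(np.asarray(h, dtype=bool), index=df.index) for h in marker_hits], axis=1
    ).fillna(False).any(axis=1)
    out = hit.astype(object)
    out[~any_seen] = np.nan
    return out


def classify_dr_frame(df: pd.DataFrame, dm: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_dr`: worse eye, other-eye imputation.

    NA where DM status is unknown or a DM participant has no gradable eye.
    """
    left = df["etdrs_grade_left"]
    right = df["etdrs_grade_right"]
    worse = pd.concat([left, right], axis=1).max(axis=1)  # NaN-skipping max
    has_eye = left.notna() | right.notna()
    out = pd.Series(np.where(worse >= DR_MIN_GRADE, True, False), index=df.index, dtype=object)
    out[dm.isna()] = np.nan
    out[dm == False] = False  # noqa: E712 -- object series against NA
    out[(dm == True) & ~has_eye] = np.nan  # noqa: E712
    return out


def derive_variables(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive dm / dr / hypertension / HOMA-IR columns for a cohort table.

    Eye grades may be missing.  ``dr`` is left missing for DM participants
    with no gradable eye and for records where DM cannot be determined.
    """
    df = cohort.copy()
    dm = classify_dm_frame(df)
    df["dm"] = dm
    df["dr"] = classify_dr_frame(df, dm)
    if "sbp_mmhg" in df and "dbp_mmhg" in df:
        ok = df["sbp_mmhg"].notna() & df["dbp_mmhg"].notna()
        htn = pd.Series(np.nan, index=df.index, dtype=object)
        htn[ok] = (df.loc[ok, "sbp_mmhg"] >= 140.0) | (df.loc[ok, "dbp_mmhg"] >= 90.0)
        df["hypertension"] = htn
    if "fasting_glucose_mmol_l" in df and "fasting_insulin_uu_ml" in df:
        df["homa_ir"] = (
            df["fasting_glucose_mmol_l"] * df["fasting_insulin_uu_ml"] / 22.5
        )
    return df


@dataclass
class ExclusionReport:
    """Ordered per-step accounting of the exclusion cascade."""

    initial: int
    steps: list[tuple[str, int, int]]  # (label, n removed, n remaining)

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed", "n_remaining"])

    def __post_init__(self):
        remaining = self.initial
        for label, removed, rem in self.steps:
            if rem != remaining - removed:
                raise ValueError(f"inconsistent counts at step {label!r}")
            remaining = rem


#: Columns required at each exclusion step, in cascade order.
DEMOGRAPHIC_COLS = ("sex", "race_ethnicity", "education", "pir", "marital")
OTHER_COVARIATE_COLS = (
    "physical_activity", "hei2015", "drinking", "smoking", "bmi",
    "cvd_history", "hypertension",
)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequential exclusion cascade; each record removed at most once.

    Step 1 drops records with no gradable eye or any missing clock
    biomarker; step 2 drops missing demographics; step 3 drops missing
    remaining covariates.  A record failing several steps counts at the
    earliest.  Returns the analytic cohort and an :class:`ExclusionReport`.
    """
    df = cohort
    n0 = len(df)
    no_eye = df["etdrs_grade_left"].isna() & df["etdrs_grade_right"].isna()
    clock_cols = sorted(set(KDM_BIOMARKERS) | set(PHENOAGE_BIOMARKERS) | {"ca_years"})
    present = [c for c in clock_cols if c in df.columns]
    bad_clock = df[present].isna().any(axis=1)
    step1 = no_eye | bad_clock
    df1 = df.loc[~step1]

    demo = [c for c in DEMOGRAPHIC_COLS if c in df.columns]
    step2 = df1[demo].isna().any(axis=1)
    df2 = df1.loc[~step2]

    other = [c for c in OTHER_COVARIATE_COLS if c in df.columns]
    step3 = df2[other].isna().any(axis=1)
    df3 = df2.loc[~step3]

    report = ExclusionReport(
        initial=n0,
        steps=[
            ("missing retinal imaging or clock biomarkers", int(step1.sum()), len(df1)),
            ("missing demographics", int(step2.sum()), len(df2)),
            ("missing other covariates", int(step3.sum()), len(df3)),
        ],
    )
    return df3, report
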