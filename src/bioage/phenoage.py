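"""Phenotypic Age (PhenoAge): a mortality-hazard-derived biological age.

PhenoAge maps nine routine blood biomarkers plus chronological age onto the
age scale through a fixed linear score ``xb`` (trained elsewhere on NHANES III
mortality follow-up via a Gompertz proportional-hazards model) and a published
closed-form transformation.  The coefficients are constants of the method and
are not re-estimated here.

Units matter: albumin in g/L, creatinine in umol/L, glucose in mmol/L, CRP
entered as the natural log of the concentration in mg/dL, lymphocytes as a
percentage of white cells, mean cell volume in fL, red-cell distribution
width in %, alkaline phosphatase in U/L, white-cell count in 1000 cells/uL,
and chronological age in years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "PHENOAGE_COEFFICIENTS",
    "PHENOAGE_BIOMARKERS",
    "compute_xb",
    "compute_phenoage",
    "phenoage_from_biomarkers",
    "phenoage_acceleration",
]

#: Linear-score coefficients, keyed by input name.  One authoritative table;
#: everything else reads from it.
PHENOAGE_COEFFICIENTS: Mapping[str, float] = {
    "intercept": -19.907,
    "albumin_g_l": -0.0336,
    "creatinine_umol_l": 0.0095,
    "glucose_mmol_l": 0.1953,
    "ln_crp_mg_dl": 0.0954,
    "lymphocyte_pct": -0.0120,
    "mcv_fl": 0.0268,
    "rdw_pct": 0.3306,
    "alk_phos_u_l": 0.00188,
    "wbc_1000_cells_ul": 0.0554,
    "ca_years": 0.0804,
}

#: The nine biomarker inputs (chronological age enters separately).
PHENOAGE_BIOMARKERS = tuple(
    k for k in PHENOAGE_COEFFICIENTS if k not in ("intercept", "ca_years")
)

# Outer constants of the published closed form
#   PA = 141.50 + ln(-B * ln(exp(-C * exp(xb) / D))) / A
_A = 0.09165
_B = 0.00553  # enters with a leading minus sign in the printed form
_C = 1.51714
_D = 0.0076927

#: ln(B*C/D); the closed form collapses to PA = 141.50 + (xb + _LOG_BCD) / A.
_LOG_BCD = float(np.log(_B * _C / _D))


def compute_xb(inputs: Mapping[str, float] | None = None, **fields: float):
    """Evaluate the PhenoAge linear score xb.

    Parameters
    ----------
    inputs
        Mapping with the nine biomarker keys of :data:`PHENOAGE_COEFFICIENTS`
        plus ``ca_years``.  Keyword arguments may be used instead of (or to
        override) the mapping.  Values may be scalars or numpy arrays.

    Returns
    -------
    float or ndarray
        The unitless linear predictor.

    Raises
    ------
    ValueError
        If any required field is missing (listing the missing names).
    """
    merged = dict(inputs or {})
    merged.update(fields)
    required = [k for k in PHENOAGE_COEFFICIENTS if k != "intercept"]
    missing = [k for k in required if k not in merged or merged[k] is None]
    if missing:
        raise ValueError(f"missing PhenoAge inputs: {', '.join(sorted(missing))}")
    xb = PHENOAGE_COEFFICIENTS["intercept"]
    for name in required:
        xb = xb + PHENOAGE_COEFFICIENTS[name] * np.asarray(merged[name])
    return xb


def compute_phenoage(xb):
    """Transform the linear score to Phenotypic Age in years.

    The published nested form is
    ``141.50 + ln(-0.00553 * ln(exp(-1.51714 * exp(xb) / 0.0076927))) / 0.09165``.
    Because ``ln(exp(z)) = z`` the nesting collapses algebraically to the
    affine map ``141.50 + (xb + ln(0.00553*1.51714/0.0076927)) / 0.09165``,
    which is what is evaluated here: the literal nesting underflows in double
    precision once ``exp(xb)`` is large enough to drive the inner ``exp`` to
    zero (xb above about -3.5), while the affine form is exact everywhere.
    """
    xb = np.asarray(xb, dtype=float)
    if not np.all(np.isfinite(xb)):
        raise ValueError("xb must be finite")
    out = 141.50 + (xb + _LOG_BCD) / _A
    return float(out) if out.ndim == 0 else out


def phenoage_from_biomarkers(inputs: Mapping[str, float] | None = None, **fields):
    """Convenience composition: biomarkers + CA -> PhenoAge in years."""
    return compute_phenoage(compute_xb(inputs, **fields))


def phenoage_acceleration(pa, ca):
    """Phenotypic age acceleration: strictly older than chronological age."""
    return np.asarray(pa) > np.asarray(ca)
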