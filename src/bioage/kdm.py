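"""Klemera-Doubal biological age (KDM BA).

The estimator combines m biomarkers, each regressed individually on
chronological age (CA) in a training sample, into a precision-weighted
age estimate:

* Step 1 fits ``x_j = q_j + k_j * CA`` per biomarker, keeping the slope
  ``k_j``, intercept ``q_j``, root mean squared error ``s_j`` and variance
  explained ``r2_j``.
* Step 2 inverts the fits into the biomarker-only estimate
  ``BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j (k_j / s_j)^2``.
* Step 3 summarises biomarker-age correlation into ``r_char`` and a scaling
  variance ``S_BA^2`` that controls how strongly CA pulls on the estimate.
* Step 4 shrinks BA_E toward CA:
  ``BA = (sum_j (x_j - q_j) k_j / s_j^2 + CA / S_BA^2)
        / (sum_j (k_j / s_j)^2 + 1 / S_BA^2)``,
  a convex combination of BA_E and CA.

Regressions run biomarker-on-age (not the inverted direction used by some
KDM variants), and may optionally be weighted by survey weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KDMParams",
    "BAResult",
    "DegenerateFitError",
    "fit_biomarker_regressions",
    "compute_ba_e",
    "compute_r_char",
    "compute_s_ba2",
    "compute_ba",
    "fit_kdm",
    "KDM_S_BA2_FLOOR",
]

#: Floor applied to S_BA^2 (years^2) when Eq. 3 yields a non-positive value.
KDM_S_BA2_FLOOR = 1e-6

#: Relative floor on per-biomarker RMSE, as a fraction of the biomarker SD.
_S_REL_FLOOR = 1e-8


class DegenerateFitError(ValueError):
    """A biomarker regression or KDM scaling step is numerically degenerate."""


@dataclass
class KDMParams:
    """Trained KDM parameters.

    Attributes
    ----------
    biomarkers : names, order fixed
    k, q, s, r2 : per-biomarker slope, intercept, RMSE, variance explained
    r_char : characteristic correlation coefficient (filled by training)
    s_ba2 : CA-shrinkage variance in years^2 (filled by training)
    ca_min, ca_max : training CA range in years
    n : training-sample size
    """

    biomarkers: tuple
    k: np.ndarray
    q: np.ndarray
    s: np.ndarray
    r2: np.ndarray
    ca_min: float
    ca_max: float
    n: int
    r_char: float | None = None
    s_ba2: float | None = None

    @property
    def m(self) -> int:
        return len(self.biomarkers)

    def to_series(self) -> pd.Series:
        """Flat key-value view (portable, diffable clock file)."""
        out = {}
        for j, name in enumerate(self.biomarkers):
            for sym, arr in (("k", self.k), ("q", self.q), ("s", self.s), ("r2", self.r2)):
                out[f"{sym}.{name}"] = arr[j]
        out.update(
            ca_min=self.ca_min, ca_max=self.ca_max, n=self.n,
            r_char=self.r_char, s_ba2=self.s_ba2,
        )
        return pd.Series(out)

    def save(self, path) -> None:
        self.to_series().to_csv(path, header=False, sep="\t")

    @classmethod
    def load(cls, path) -> "KDMParams":
        s = pd.read_csv(path, header=None, index_col=0, sep="\t")[1]
        names = tuple(k.split(".", 1)[1] for k in s.index if k.startswith("k."))
        get = lambda sym: np.array([s[f"{sym}.{nm}"] for nm in names], dtype=float)
        return cls(
            biomarkers=names, k=get("k"), q=get("q"), s=get("s"), r2=get("r2"),
            ca_min=float(s["ca_min"]), ca_max=float(s["ca_max"]), n=int(s["n"]),
            r_char=float(s["r_char"]), s_ba2=float(s["s_ba2"]),
        )


@dataclass
class BAResult:
    """Final KDM estimate for one subject (or a vector of subjects)."""

    ba_e: float | np.ndarray
    ba: float | np.ndarray
    accelerated: bool | np.ndarray


def _as_xmat(x, biomarkers) -> np.ndarray:
    """Coerce dict / Series / DataFrame / array input to an (n, m) matrix."""
    if isinstance(x, (dict, pd.Series)):
        missing = [b for b in biomarkers if b not in x or pd.isna(x[b])]
        if missing:
            raise ValueError(f"missing biomarkers: {', '.join(missing)}")
        return np.asarray([x[b] for b in biomarkers], dtype=float)[None, :]
    if isinstance(x, pd.DataFrame):
        missing = [b for b in biomarkers if b not in x.columns]
        if missing:
            raise ValueError(f"missing biomarkers: {', '.join(missing)}")
        mat = x.loc[:, list(biomarkers)].to_numpy(dtype=float)
    else:
        mat = np.atleast_2d(np.asarray(x, dtype=float))
    if mat.shape[1] != len(biomarkers):
        raise ValueError(
            f"expected {len(biomarkers)} biomarkers, got {mat.shape[1]}"
        )
    if np.isnan(mat).any():
        raise ValueError("biomarker matrix contains missing values")
    return mat


def fit_biomarker_regressions(
    training: pd.DataFrame,
    biomarkers: Sequence[str],
    ca_col: str = "ca_years",
    weights: np.ndarray | None = None,
) -> KDMParams:
    """Step 1: per-biomarker (optionally weighted) least squares on CA.

    ``s_j`` is the root mean squared residual and ``r2_j`` the squared
    (weighted) correlation between biomarker and CA.  Raises
    :class:`DegenerateFitError` for constant biomarkers or fits whose
    residual scale collapses below a relative floor.
    """
    ca = training[ca_col].to_numpy(dtype=float)
    if len(np.unique(ca)) < 3:
        raise DegenerateFitError("need at least 3 distinct CA values to train")
    w = np.ones_like(ca) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != ca.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and aligned with training rows")
    wsum = w.sum()
    ca_bar = np.sum(w * ca) / wsum
    ss_ca = np.sum(w * (ca - ca_bar) ** 2)

    k = np.empty(len(biomarkers))
    q = np.empty_like(k)
    s = np.empty_like(k)
    r2 = np.empty_like(k)
    for j, name in enumerate(biomarkers):
        x = training[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"biomarker {name!r} has missing values in training data")
        x_bar = np.sum(w * x) / wsum
        sxx = np.sum(w * (x - x_bar) ** 2)
        if sxx <= 0:
            raise DegenerateFitError(f"biomarker {name!r} is constant in training data")
        sxy = np.sum(w * (x - x_bar) * (ca - ca_bar))
        k[j] = sxy / ss_ca
        q[j] = x_bar - k[j] * ca_bar
        resid = x - (q[j] + k[j] * ca)
        s[j] = np.sqrt(np.sum(w * resid**2) / wsum)
        r2[j] = sxy**2 / (sxx * ss_ca)
        sd_x = np.sqrt(sxx / wsum)
        if s[j] < _S_REL_FLOOR * sd_x or s[j] == 0.0:
            raise DegenerateFitError(
                f"biomarker {name!r}: residual scale {s[j]:.3g} below floor "
                f"(perfect fit on CA)"
            )
        if k[j] == 0.0:
            raise DegenerateFitError(f"biomarker {name!r}: zero slope on CA")
    return KDMParams(
        biomarkers=tuple(biomarkers), k=k, q=q, s=s, r2=r2,
        ca_min=float(ca.min()), ca_max=float(ca.max()), n=len(ca),
    )


def compute_ba_e(x, params: KDMParams):
    """Step 2: the biomarker-only optimum age estimate BA_E (years)."""
    mat = _as_xmat(x, params.biomarkers)
    num = (mat - params.q) @ (params.k / params.s**2)
    den = np.sum((params.k / params.s) ** 2)
    out = num / den
    return float(out[0]) if out.shape == (1,) else out


def compute_r_char(params: KDMParams) -> float:
    """Step 3a: characteristic correlation coefficient.

    ``r_char = sum(r^2 / sqrt(1 - r^2)) / sum(r / sqrt(1 - r^2))`` with
    ``r_j = +sqrt(r2_j)``.
    """
    r = np.sqrt(params.r2)
    if np.any(r >= 1.0):
        raise DegenerateFitError("a biomarker correlates perfectly with CA (r = 1)")
    g = 1.0 / np.sqrt(1.0 - r**2)
    return float(np.sum(r**2 * g) / np.sum(r * g))


def compute_s_ba2(ba_e, ca, params: KDMParams, r_char: float | None = None) -> float:
    """Step 3b: the CA-shrinkage variance S_BA^2 (years^2).

    Population variance (divisor n) of the per-subject deviation
    ``BA_E,i - CA_i`` about its own mean, minus the explained-range term
    ``(1 - r_char^2) / r_char^2 * (CA_max - CA_min)^2 / (12 m)``.  A
    non-positive result is floored at :data:`KDM_S_BA2_FLOOR` with a warning.
    """
    ba_e = np.asarray(ba_e, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if ba_e.shape != ca.shape or ba_e.size < 2:
        raise ValueError("ba_e and ca must be aligned vectors of length >= 2")
    rc = compute_r_char(params) if r_char is None else r_char
    if rc == 0:
        raise DegenerateFitError("r_char is zero; S_BA^2 undefined")
    diff = ba_e - ca
    var_term = float(np.mean((diff - diff.mean()) ** 2))
    range_term = ((1.0 - rc**2) / rc**2) * (params.ca_max - params.ca_min) ** 2 / (12.0 * params.m)
    s_ba2 = var_term - range_term
    if s_ba2 <= 0:
        warnings.warn(
            f"S_BA^2 = {s_ba2:.4g} <= 0; flooring at {KDM_S_BA2_FLOOR}. "
            "The biomarker set explains less age variance than its noise term.",
            RuntimeWarning,
            stacklevel=2,
        )
        s_ba2 = KDM_S_BA2_FLOOR
    return float(s_ba2)


def compute_ba(x, ca, params: KDMParams) -> BAResult:
    """Step 4: final BA, a precision-weighted blend of BA_E and CA.

    ``accelerated`` flags BA strictly greater than CA.
    """
    if params.s_ba2 is None or params.s_ba2 <= 0:
        raise DegenerateFitError("params.s_ba2 missing or non-positive; train first")
    mat = _as_xmat(x, params.biomarkers)
    ca_arr = np.atleast_1d(np.asarray(ca, dtype=float))
    num = (mat - params.q) @ (params.k / params.s**2) + ca_arr / params.s_ba2
    den = np.sum((params.k / params.s) ** 2) + 1.0 / params.s_ba2
    ba = num / den
    ba_e = compute_ba_e(mat, params)
    scalar = np.isscalar(ca) and mat.shape[0] == 1
    if scalar:
        ba = float(ba[0])
        ca_arr = float(ca_arr[0])
        ba_e = float(np.atleast_1d(ba_e)[0])
    return BAResult(ba_e=ba_e, ba=ba, accelerated=np.asarray(ba) > np.asarray(ca_arr))


def fit_kdm(
    training: pd.DataFrame,
    biomarkers: Sequence[str],
    ca_col: str = "ca_years",
    weights: np.ndarray | None = None,
) -> KDMParams:
    """Train the full clock (Steps 1-3) on one table; returns complete params."""
    params = fit_biomarker_regressions(training, biomarkers, ca_col, weights)
    params.r_char = compute_r_char(params)
    ba_e = compute_ba_e(training, params)
    params.s_ba2 = compute_s_ba2(ba_e, training[ca_col].to_numpy(dtype=float), params, params.r_char)
    return params
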