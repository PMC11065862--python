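"""Restricted cubic spline dose-response curves in the survey-logistic model.

Three knots at the (weighted) 10th/50th/90th percentiles give one linear and
one restricted cubic column (Harrell's truncated-power basis, normalized by
the squared outer-knot span).  The fitted curve is reported as an odds ratio
relative to a reference exposure value with pointwise design-based CIs; the
nonlinearity test is the Wald test of the cubic coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survey import (
    SurveyDesign,
    build_design_matrix,
    fit_survey_logistic,
    or_ci,
    weighted_quantile,
)
from scipy import stats

__all__ = ["RCSBasis", "make_knots", "rcs_basis", "fit_spline_curve", "SplineCurve"]


@dataclass
class RCSBasis:
    """Knots plus the evaluated [linear, restricted-cubic] basis matrix."""

    knots: tuple[float, float, float]
    matrix: np.ndarray  # (n, 2)


def make_knots(x, weights=None) -> tuple[float, float, float]:
    """Knots at the 10th/50th/90th percentiles (weighted when given)."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 10:
        raise ValueError("need at least 10 distinct exposure values for knots")
    if weights is None:
        knots = np.percentile(x, [10, 50, 90])
    else:
        knots = weighted_quantile(x, [0.10, 0.50, 0.90], weights)
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise ValueError(f"ties collapse the knots: {(k1, k2, k3)}")
    return k1, k2, k3


def rcs_basis(x, knots: Sequence[float]) -> RCSBasis:
    """Harrell restricted truncated-power basis for 3 knots.

    The single nonlinear column is
    ``[(x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2)]
    / (k3-k1)^2``: zero below k1 and exactly linear beyond k3, with
    continuous first and second derivatives everywhere.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("exposure contains non-finite values")
    k1, k2, k3 = knots
    if not (k1 < k2 < k3):
        raise ValueError("knots must be strictly increasing")
    p = lambda v: np.clip(v, 0.0, None) ** 3
    cub = (
        p(x - k1)
        - p(x - k2) * (k3 - k1) / (k3 - k2)
        + p(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return RCSBasis(knots=(k1, k2, k3), matrix=np.column_stack([x, cub]))


@dataclass
class SplineCurve:
    """Dose-response output: OR(x) vs the reference, with pointwise CI."""

    curve: pd.DataFrame  # columns x, or, lo, hi
    reference: float
    knots: tuple[float, float, float]
    p_nonlinearity: float
    fit: object


def fit_spline_curve(
    data: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str],
    design: SurveyDesign,
    reference: float | None = None,
    grid: np.ndarray | None = None,
    knots: Sequence[float] | None = None,
) -> SplineCurve:
    """Survey-logistic spline fit for one exposure.

    ``reference`` defaults to the weighted median of the exposure; ``grid``
    defaults to 100 points spanning the weighted 1st-99th percentiles.
    ``OR(x) = exp(eta(x) - eta(ref))`` using only the exposure's two basis
    coefficients, so covariates held fixed cancel; the CI uses the
    design-based covariance of that contrast and the design-df t quantile.
    """
    x = data[exposure].to_numpy(dtype=float)
    w = design.weights
    if knots is None:
        knots = make_knots(x, w)
    basis = rcs_basis(x, knots)
    lin_col, cub_col = f"{exposure}__lin", f"{exposure}__cub"
    d2 = data.copy()
    d2[lin_col] = basis.matrix[:, 0]
    d2[cub_col] = basis.matrix[:, 1]
    fit = fit_survey_logistic(outcome, [lin_col, cub_col, *covariates], design, d2)
    p_nl = or_ci(fit, cub_col)["p"]

    if reference is None:
        reference = float(weighted_quantile(x, 0.5, w))
    if grid is None:
        lo, hi = weighted_quantile(x, [0.01, 0.99], w)
        grid = np.linspace(lo, hi, 100)
    grid = np.asarray(grid, dtype=float)

    bg = rcs_basis(grid, knots).matrix
    br = rcs_basis(np.array([reference]), knots).matrix
    contrast = bg - br  # (g, 2)
    idx = [fit.term_index(lin_col), fit.term_index(cub_col)]
    beta = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    eta = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, V, contrast))
    tcrit = stats.t.ppf(0.975, fit.df)
    curve = pd.DataFrame({
        "x": grid,
        "or": np.exp(eta),
        "lo": np.exp(eta - tcrit * se),
        "hi": np.exp(eta + tcrit * se),
    })
    return SplineCurve(curve=curve, reference=reference, knots=tuple(knots),
                       p_nonlinearity=p_nl, fit=fit)
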