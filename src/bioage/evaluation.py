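"""Discrimination and clinical utility of candidate DR predictors.

ROC / C-statistic (via scikit-learn's trapezoidal curve, which equals the
Mann-Whitney pair count with ties scored 0.5) and decision-curve analysis
net benefit.  Both accept optional weights: the weighted AUC is the
weight-product concordance, and weighted net benefit replaces counts with
weight sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .survey import SurveyDesign, fit_survey_logistic, _covariates_for

__all__ = [
    "ROCResult",
    "DCAResult",
    "roc_auc",
    "decision_curve",
    "compare_predictors",
    "DEFAULT_DCA_THRESHOLDS",
]

#: Decision-curve threshold-probability grid.
DEFAULT_DCA_THRESHOLDS = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class DCAResult:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    net_benefit_all: np.ndarray  # treat-all reference
    net_benefit_none: np.ndarray  # identically zero
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "nb_model": self.net_benefit,
            "nb_treat_all": self.net_benefit_all,
            "nb_treat_none": self.net_benefit_none,
        })


def roc_auc(scores, labels, weights=None) -> ROCResult:
    """ROC curve and C-statistic.

    AUC is the probability a random case outranks a random control (ties at
    0.5); with weights, pairs are weighted by the product of case and
    control weights.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = roc_curve(y, s, sample_weight=weights)
    auc = float(roc_auc_score(y, s, sample_weight=weights))
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def decision_curve(
    pred_prob, labels, thresholds=None, weights=None
) -> DCAResult:
    """Net benefit over a threshold-probability grid.

    ``NB(p_t) = TP/n - FP/n * p_t/(1-p_t)`` classifying positive at
    ``pred_prob >= p_t``; treat-all and treat-none references included.
    With weights, counts become weight sums and n the total weight.
    """
    p = np.asarray(pred_prob, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = DEFAULT_DCA_THRESHOLDS
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n = w.sum()
    prev = float(np.sum(w * y) / n)
    pos = p[None, :] >= t[:, None]  # (T, n)
    tp = (pos * (w * y)[None, :]).sum(axis=1) / n
    fp = (pos * (w * (1 - y))[None, :]).sum(axis=1) / n
    odds = t / (1 - t)
    nb = tp - fp * odds
    nb_all = prev - (1 - prev) * odds
    return DCAResult(
        thresholds=t, net_benefit=nb, net_benefit_all=nb_all,
        net_benefit_none=np.zeros_like(t), prevalence=prev,
    )


def compare_predictors(
    data: pd.DataFrame,
    design: SurveyDesign,
    exposures: Sequence[str] = ("ba_years", "pa_years", "ca_years"),
    outcome: str = "dr",
    adjusted: bool = True,
    weighted: bool = False,
    thresholds=None,
) -> dict[str, dict]:
    """Per-exposure ROC + DCA from fitted model probabilities.

    By default each exposure is scored through its covariate-adjusted
    (Model-3) survey-logistic fit and the fitted probabilities on the
    analytic sample feed both curves; ``adjusted=False`` instead fits the
    crude single-exposure model.  ``weighted=True`` applies survey weights
    to the AUC and net-benefit estimators.
    """
    out = {}
    w = design.weights if weighted else None
    y = data[outcome].to_numpy(dtype=int)
    for exp_col in exposures:
        covs = _covariates_for(exp_col, 3) if adjusted else []
        fit = fit_survey_logistic(outcome, [exp_col, *covs], design, data)
        probs = fit.fitted
        out[exp_col] = {
            "fit": fit,
            "roc": roc_auc(probs, y, weights=w),
            "dca": decision_curve(probs, y, thresholds=thresholds, weights=w),
        }
    return out
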