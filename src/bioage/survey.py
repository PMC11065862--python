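"""Design-based estimation for stratified multistage samples.

Implements the estimators a complex health survey such as NHANES requires:
Horvitz-Thompson ratio means with Taylor-linearized standard errors,
weighted contingency tables with Rao-Scott second-order corrected
chi-squared tests, and weighted-likelihood logistic regression whose
covariance is the linearization sandwich built from between-PSU variation
of score totals within strata.

Conventions (documented knobs, since surveys differ):

* Variance strata with a single PSU ("lonely PSU") contribute their PSU
  total centred at the grand mean of all PSU totals, with a warning.
* Wald inference uses a t reference with ``df = #PSUs - #strata``.
* Estimation is invariant to rescaling all weights by a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "SurveyDesign",
    "LogisticFit",
    "ConvergenceError",
    "weighted_mean_se",
    "weighted_quantile",
    "weighted_table",
    "domain_mean_ttest",
    "rao_scott_chi2",
    "build_design_matrix",
    "fit_survey_logistic",
    "or_ci",
    "wald_joint_test",
    "trend_test",
    "interaction_test",
    "model_suite",
    "subgroup_analysis",
]


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (separation or ill-conditioning)."""


@dataclass
class SurveyDesign:
    """Stratum / PSU / weight triplets defining the variance structure.

    PSU identifiers are interpreted within stratum, so reusing PSU label
    "1" in two strata denotes two distinct sampling units.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValueError("strata, psu and weights must be aligned")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and strictly positive")
        # integer codes for fast grouping
        pair = pd.MultiIndex.from_arrays([self.strata, self.psu])
        self._psu_code, uniq = pd.factorize(pair, sort=True)
        self._stratum_of_psu = pd.factorize(uniq.get_level_values(0), sort=True)[0]
        self.n_psu = len(uniq)
        self.n_strata = len(np.unique(self._stratum_of_psu))

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psu - self.n_strata

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stratum="stratum", psu="psu", weight="weight"):
        return cls(df[stratum].to_numpy(), df[psu].to_numpy(), df[weight].to_numpy())

    def subset(self, mask) -> "SurveyDesign":
        """Domain (subpopulation) design: rows restricted to ``mask`` but the
        full stratum/PSU inventory retained, so variance estimation counts
        PSUs with no domain members as zero totals (proper domain
        estimation, rather than pretending the domain was the sample)."""
        mask = np.asarray(mask)
        d = SurveyDesign(self.strata[mask], self.psu[mask], self.weights[mask])
        d._psu_code = self._psu_code[mask]
        d._stratum_of_psu = self._stratum_of_psu
        d.n_psu = self.n_psu
        d.n_strata = self.n_strata
        return d

    def linearized_factor(self, influence: np.ndarray) -> np.ndarray:
        """Square-root factor Z of the covariance of a total: cov = Z'Z.

        Rows of Z are the per-PSU influence totals, centred at their stratum
        mean and scaled by ``sqrt(n_h/(n_h-1))``.  Lonely-PSU strata are
        centred at the grand mean of PSU totals (with a warning).  Returning
        the factor lets callers build sandwich covariances that are positive
        semidefinite by construction.
        """
        z = np.atleast_2d(np.asarray(influence, dtype=float))
        if z.shape[0] != len(self):
            z = z.T
        p = z.shape[1]
        totals = np.zeros((self.n_psu, p))
        np.add.at(totals, self._psu_code, z)
        grand = totals.mean(axis=0)
        rows = np.empty_like(totals)
        lonely = 0
        for h in np.unique(self._stratum_of_psu):
            sel = self._stratum_of_psu == h
            t_h = totals[sel]
            n_h = t_h.shape[0]
            if n_h == 1:
                lonely += 1
                rows[sel] = t_h - grand
            else:
                rows[sel] = np.sqrt(n_h / (n_h - 1)) * (t_h - t_h.mean(axis=0))
        if lonely:
            warnings.warn(
                f"{lonely} stratum/strata with a single PSU; centring at "
                "the grand mean of PSU totals",
                RuntimeWarning,
                stacklevel=3,
            )
        return rows

    def linearized_cov(self, influence: np.ndarray) -> np.ndarray:
        """Covariance of a total from per-record influence (score) vectors:
        stratified between-PSU Taylor linearization."""
        Z = self.linearized_factor(influence)
        return Z.T @ Z


# ---------------------------------------------------------------------------
# descriptives


def weighted_mean_se(x, design: SurveyDesign) -> tuple[float, float]:
    """Horvitz-Thompson ratio mean with linearized SE."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != len(design):
        raise ValueError("x and design must be aligned")
    w = design.weights
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    infl = (w * (x - mean) / wsum)[:, None]
    se = float(np.sqrt(design.linearized_cov(infl)[0, 0]))
    return mean, se


def weighted_quantile(x, q, weights) -> float | np.ndarray:
    """Weighted quantile(s) by inverse of the weighted empirical CDF.

    Linear interpolation on the weighted analogue of plotting positions
    ``(cumw - w/2) / sumw``, which reduces to a numpy-like interpolated
    quantile for equal weights.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(q, cum, x)


def weighted_table(values, design: SurveyDesign) -> pd.DataFrame:
    """Per-level weighted percentages and unweighted counts."""
    s = pd.Series(np.asarray(values))
    w = pd.Series(design.weights)
    grp = w.groupby(s.to_numpy()).sum()
    pct = 100.0 * grp / grp.sum()
    n = s.value_counts()
    out = pd.DataFrame({"n": n, "weighted_pct": pct}).sort_index()
    out.index.name = "level"
    return out


def domain_mean_ttest(x, domain, design: SurveyDesign) -> dict:
    """Design-based t-test of a difference in domain means.

    ``domain`` is a boolean split (e.g. with / without the outcome).  The
    difference of the two Horvitz-Thompson domain means is linearized
    jointly, giving an SE that honours strata and clustering; the p-value
    uses the design df.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(domain, dtype=bool)
    w = design.weights
    if not (d.any() and (~d).any()):
        raise ValueError("both domains must be non-empty")
    w1, w0 = np.sum(w[d]), np.sum(w[~d])
    m1 = np.sum(w[d] * x[d]) / w1
    m0 = np.sum(w[~d] * x[~d]) / w0
    infl = np.where(d, w * (x - m1) / w1, 0.0) - np.where(~d, w * (x - m0) / w0, 0.0)
    se = float(np.sqrt(design.linearized_cov(infl[:, None])[0, 0]))
    t = (m1 - m0) / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), design.df)
    return {"mean_1": m1, "mean_0": m0, "diff": m1 - m0, "se": se, "t": t, "p": float(p)}


def rao_scott_chi2(rows, cols, design: SurveyDesign) -> tuple[float, float]:
    """Rao-Scott second-order (Satterthwaite) corrected chi-squared test.

    The Pearson statistic is computed on the weighted cell proportions with
    the unweighted sample size n.  Its asymptotic null law is a weighted sum
    of chi-squared(1) variables whose weights are the generalized design
    effects: the non-trivial eigenvalues of
    ``n * M^{1/2} J V J' M^{1/2}``, with V the linearized covariance of the
    cell-proportion estimates, J the Jacobian of the independence residuals
    ``h_ij = p_ij - p_i. p_.j`` and M = diag(1/(p_i. p_.j)).  The
    second-order correction refers ``X^2 / (dbar (1 + a^2))`` to a
    chi-squared with ``d / (1 + a^2)`` degrees of freedom, where dbar is the
    mean eigenvalue and a their coefficient of variation.

    Returns ``(corrected statistic, p value)``.
    """
    r = pd.Series(np.asarray(rows))
    c = pd.Series(np.asarray(cols))
    r_codes, r_lvls = pd.factorize(r.to_numpy(), sort=True)
    c_codes, c_lvls = pd.factorize(c.to_numpy(), sort=True)
    R, C = len(r_lvls), len(c_lvls)
    if R < 2 or C < 2:
        raise ValueError("need at least 2 levels in each margin")
    n = len(r)
    w = design.weights
    cell = r_codes * C + c_codes
    K = R * C
    # weighted cell proportions
    wtot = w.sum()
    p_hat = np.zeros(K)
    np.add.at(p_hat, cell, w)
    p_hat /= wtot
    if np.any(p_hat.reshape(R, C).sum(axis=1) == 0) or np.any(
        p_hat.reshape(R, C).sum(axis=0) == 0
    ):
        raise ValueError("empty margin; collapse levels first")
    p_r = p_hat.reshape(R, C).sum(axis=1)
    p_c = p_hat.reshape(R, C).sum(axis=0)
    p0 = np.outer(p_r, p_c).ravel()
    h = p_hat - p0
    x2 = n * float(np.sum(h**2 / p0))

    # linearized covariance of p_hat (ratio estimator per cell)
    ind = np.zeros((n, K))
    ind[np.arange(n), cell] = 1.0
    infl = (w[:, None] * (ind - p_hat)) / wtot
    V = design.linearized_cov(infl)
    # Jacobian of h wrt p: dh_ij/dp_kl = 1{ij=kl} - 1{i=k} p_.j - 1{j=l} p_i.
    J = np.eye(K)
    for i in range(R):
        for jj in range(C):
            row = i * C + jj
            J[row, i * C : (i + 1) * C] -= p_c[jj]
            J[row, jj::C] -= p_r[i]
    Vh = J @ V @ J.T
    Msqrt = 1.0 / np.sqrt(p0)
    A = n * (Msqrt[:, None] * Vh * Msqrt[None, :])
    d = (R - 1) * (C - 1)
    eig = np.sort(np.linalg.eigvalsh((A + A.T) / 2))[::-1][:d]
    eig = np.clip(eig, 0.0, None)
    dbar = eig.mean()
    if dbar <= 0:
        return 0.0, 1.0
    a2 = float(np.sum((eig - dbar) ** 2) / (d * dbar**2))
    stat = x2 / (dbar * (1 + a2))
    df_adj = d / (1 + a2)
    p = float(stats.chi2.sf(stat, df_adj))
    return float(stat), p


# ---------------------------------------------------------------------------
# design matrices


def build_design_matrix(
    data: pd.DataFrame, terms: Sequence[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Expand a term list into a numeric design matrix.

    Numeric columns enter as-is; object/categorical/boolean columns are
    dummy-expanded against their first (sorted or declared) level.  Terms of
    the form ``"a:b"`` denote a product of the two expanded columns.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(data)))
        names.append("(Intercept)")

    def expand(term: str) -> tuple[list[np.ndarray], list[str]]:
        if ":" in term:
            a, b = term.split(":", 1)
            ca_, na_ = expand(a)
            cb_, nb_ = expand(b)
            prod_c, prod_n = [], []
            for x, nx in zip(ca_, na_):
                for y, ny in zip(cb_, nb_):
                    prod_c.append(x * y)
                    prod_n.append(f"{nx}:{ny}")
            return prod_c, prod_n
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in data")
        col = data[term]
        if col.isna().any():
            raise ValueError(f"term {term!r} has missing values")
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        elif col.dtype == object or col.dtype == bool:
            levels = sorted(pd.unique(col))
        else:
            return [col.to_numpy(dtype=float)], [term]
        if len(levels) < 2:
            raise ValueError(f"categorical term {term!r} has a single level")
        arrs = [(col == lv).to_numpy(dtype=float) for lv in levels[1:]]
        return arrs, [f"{term}[{lv}]" for lv in levels[1:]]

    for term in terms:
        c, nms = expand(term)
        cols.extend(c)
        names.extend(nms)
    X = np.column_stack(cols)
    return X, names


# ---------------------------------------------------------------------------
# survey-weighted logistic regression


@dataclass
class LogisticFit:
    """A weighted-likelihood logistic fit with design-based covariance.

    ``df`` is the inference df for single-coefficient t tests,
    ``design df - p + 1`` with p the number of estimated coefficients (the
    convention of R's svyglm); ``df_design`` is the raw #PSUs - #strata.
    """

    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    df: int
    n: int
    converged: bool
    n_iter: int
    fitted: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    df_design: int = 0

    def se(self) -> np.ndarray:
        # the sandwich diagonal can dip infinitesimally below zero in nearly
        # degenerate subgroups; clamp rather than emit NaN
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def term_index(self, term: str) -> int:
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}; have {self.terms}")
        return self.terms.index(term)

    def summary(self) -> pd.DataFrame:
        rows = [or_ci(self, t) for t in self.terms]
        return pd.DataFrame(rows, index=self.terms)

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        return self.fitted if X is None else expit(X @ self.beta)


def _newton_logistic(X, y, w, max_iter=50, tol=1e-10):
    """Weighted-likelihood Newton-Raphson with step halving."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta

    def loglik(eta):
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik(eta)
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        g = X.T @ (w * (y - mu))
        wt = w * mu * (1 - mu)
        H = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix at iter {it}: {e}")
        # step halving
        alpha = 1.0
        for _ in range(30):
            beta_new = beta + alpha * step
            ll_new = loglik(X @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2
        beta, eta, ll_prev, ll = beta_new, X @ beta_new, ll, ll_new
        if np.max(np.abs(alpha * step)) < tol or abs(ll - ll_prev) < tol * (abs(ll) + 1):
            mu = expit(eta)
            if np.max(np.abs(beta)) > 40:
                raise ConvergenceError(
                    "coefficients diverging (|beta| > 40): likely complete separation"
                )
            return beta, mu, it, True
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations; max|grad|={np.max(np.abs(g)):.3g}"
    )


def fit_survey_logistic(
    outcome: str,
    terms: Sequence[str],
    design: SurveyDesign,
    data: pd.DataFrame,
) -> LogisticFit:
    """Survey-weighted logistic regression with Taylor-linearized covariance.

    Point estimates maximize the weighted log-likelihood; the covariance is
    the sandwich ``H^{-1} G H^{-1}`` where H is the weighted observed
    information and G the between-PSU covariance of the per-record score
    contributions ``w_i (y_i - p_i) x_i`` accumulated within strata.
    """
    y = data[outcome].to_numpy(dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X, names = build_design_matrix(data, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (perfect collinearity)")
    w = design.weights
    if len(w) != len(y):
        raise ValueError("design and data must be aligned")
    # scale-free weights for numerical stability (estimates are invariant)
    w_s = w * (len(w) / w.sum())
    # equilibrate columns so conditioning reflects collinearity, not units
    scale = np.sqrt(np.mean(X**2, axis=0))
    scale[scale == 0] = 1.0
    Xs = X / scale
    beta_s, mu, n_iter, ok = _newton_logistic(Xs, y, w_s)
    H = Xs.T @ (Xs * (w_s * mu * (1 - mu))[:, None])
    eigs = np.linalg.eigvalsh((H + H.T) / 2)
    if eigs[0] <= 0 or eigs[-1] / eigs[0] > 1e14:
        raise ConvergenceError(
            f"information matrix ill-conditioned (cond ~ {eigs[-1] / max(eigs[0], 1e-300):.2g}); "
            "a covariate pattern is nearly unobserved"
        )
    scores = Xs * (w_s * (y - mu))[:, None]
    Z = design.linearized_factor(scores)
    # sandwich as (Z H^-1)'(Z H^-1): positive semidefinite by construction
    W = np.linalg.solve(H, Z.T).T
    cov_s = W.T @ W
    beta = beta_s / scale
    cov = (cov_s + cov_s.T) / 2 / np.outer(scale, scale)
    df_t = max(design.df - X.shape[1] + 1, 1)
    return LogisticFit(
        terms=names, beta=beta, cov=cov, df=df_t, n=len(y),
        converged=ok, n_iter=n_iter, fitted=mu, X=X, df_design=design.df,
    )


def or_ci(fit: LogisticFit, term: str, level: float = 0.95) -> dict:
    """Odds ratio with t-based CI and two-sided p for one term."""
    j = fit.term_index(term)
    b = fit.beta[j]
    se = fit.se()[j]
    tcrit = stats.t.ppf(0.5 + level / 2, fit.df)
    if se == 0:
        lo = hi = np.exp(b)
        p = 0.0 if b != 0 else 1.0
    else:
        lo, hi = np.exp(b - tcrit * se), np.exp(b + tcrit * se)
        p = 2 * stats.t.sf(abs(b / se), fit.df)
    return {"term": term, "beta": b, "se": se, "or": float(np.exp(b)),
            "lo": float(lo), "hi": float(hi), "p": float(p)}


def wald_joint_test(fit: LogisticFit, terms: Sequence[str]) -> dict:
    """Joint Wald test of several coefficients, F-referenced on the design df."""
    idx = [fit.term_index(t) for t in terms]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    q = len(idx)
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise ValueError("singular covariance block in joint Wald test")
    F = stat / q
    df2 = max(fit.df_design - q + 1, 1)
    p = float(stats.f.sf(F, q, df2))
    return {"F": F, "df1": q, "df2": df2, "p": p}


def trend_test(
    data: pd.DataFrame,
    outcome: str,
    ordinal_term: str,
    design: SurveyDesign,
    covariates: Sequence[str] = (),
    order: Sequence | None = None,
) -> float:
    """Linear-trend p: refit with the ordered levels coded 0,1,2,... as one
    continuous term and return its Wald p."""
    col = data[ordinal_term]
    if order is None:
        if isinstance(col.dtype, pd.CategoricalDtype) and col.cat.ordered:
            order = list(col.cat.categories)
        elif np.issubdtype(np.asarray(col).dtype, np.number):
            order = sorted(pd.unique(col))
        else:
            raise ValueError(
                f"{ordinal_term!r} has no declared order; pass `order=` or use an "
                "ordered categorical"
            )
    codes = col.map({lv: i for i, lv in enumerate(order)})
    if codes.isna().any():
        raise ValueError("levels outside the declared order")
    d2 = data.copy()
    name = f"{ordinal_term}__trend"
    d2[name] = codes.astype(float)
    fit = fit_survey_logistic(outcome, [name, *covariates], design, d2)
    return or_ci(fit, name)["p"]


def interaction_test(
    data: pd.DataFrame,
    outcome: str,
    a: str,
    b: str,
    design: SurveyDesign,
    covariates: Sequence[str] = (),
) -> float:
    """P for effect modification of `a` by `b` via cross-product terms.

    Joint Wald test of all ``a:b`` product coefficients (one per non-reference
    level of a categorical b).
    """
    nb = data[b].nunique()
    if nb < 2:
        raise ValueError(f"modifier {b!r} is constant")
    fit = fit_survey_logistic(outcome, [a, b, f"{a}:{b}", *covariates], design, data)
    prod_terms = [t for t in fit.terms if ":" in t]
    return wald_joint_test(fit, prod_terms)["p"]


MODEL2_COVARIATES = ["ca_years", "sex", "race_ethnicity", "pir", "marital", "education"]
MODEL3_EXTRA = [
    "physical_activity", "hei2015", "drinking", "smoking", "bmi",
    "cvd_history", "hypertension",
]


def _covariates_for(exposure: str, model: int, drop: Sequence[str] = ()) -> list[str]:
    if model == 1:
        covs = []
    else:
        covs = list(MODEL2_COVARIATES)
        if model == 3:
            covs += MODEL3_EXTRA
    # an exposure is never adjusted for itself; chronological-age exposures
    # (continuous or grouped) drop the age covariate
    age_like = {"ca_years", "ca_group"}
    covs = [
        c for c in covs
        if c != exposure and c not in drop and not (exposure in age_like and c in age_like)
    ]
    return covs


def model_suite(
    data: pd.DataFrame,
    design: SurveyDesign,
    exposure: str,
    outcome: str = "dr",
    extra_covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Model-1/2/3 ladder for one exposure.

    Model 1 is crude; Model 2 adds demographics (age, sex, race/ethnicity,
    PIR, marital status, education); Model 3 additionally adjusts for
    physical activity, diet score, drinking, smoking, BMI, CVD history and
    hypertension.  Chronological-age exposures omit the age covariate.
    Returns one row per exposure term per model.
    """
    if exposure in MODEL2_COVARIATES or exposure in MODEL3_EXTRA:
        if exposure not in ("ca_years",):
            raise ValueError(f"exposure {exposure!r} is also an adjusted covariate")
    rows = []
    for model in (1, 2, 3):
        covs = _covariates_for(exposure, model) + list(extra_covariates)
        fit = fit_survey_logistic(outcome, [exposure, *covs], design, data)
        for t in fit.terms:
            if t == "(Intercept)" or t.split("[")[0] != exposure:
                continue
            row = or_ci(fit, t)
            row["model"] = model
            row["exposure"] = exposure
            rows.append(row)
    return pd.DataFrame(rows)[
        ["model", "exposure", "term", "or", "lo", "hi", "p", "beta", "se"]
    ]


def subgroup_analysis(
    data: pd.DataFrame,
    design: SurveyDesign,
    exposure: str,
    strata_vars: Sequence[str],
    outcome: str = "dr",
    covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Model-3 fit per subgroup (stratifier removed from covariates) plus an
    interaction p per stratifying variable.  Degenerate subgroups (single
    outcome class, or a fit failure) are flagged rather than fatal.
    ``covariates`` overrides the default fully-adjusted covariate list."""
    rows = []
    for var in strata_vars:
        if covariates is None:
            covs = _covariates_for(exposure, 3, drop=(var,))
        else:
            covs = [c for c in covariates if c not in (var, exposure)]
        try:
            p_int = interaction_test(data, outcome, exposure, var, design, covs)
        except (ValueError, ConvergenceError) as e:
            p_int = np.nan
        for lv in sorted(pd.unique(data[var].dropna()), key=str):
            mask = (data[var] == lv).to_numpy()
            sub = data.loc[mask]
            base = {"stratifier": var, "level": lv, "exposure": exposure,
                    "n": int(mask.sum()), "p_interaction": p_int}
            if sub[outcome].nunique() < 2:
                rows.append({**base, "flag": "single outcome class"})
                continue
            try:
                fit = fit_survey_logistic(
                    outcome, [exposure, *covs], design.subset(mask), sub
                )
                row = or_ci(fit, exposure)
                rows.append({**base, "or": row["or"], "lo": row["lo"],
                             "hi": row["hi"], "p": row["p"], "flag": ""})
            except (ValueError, ConvergenceError) as e:
                rows.append({**base, "flag": f"fit failed: {e}"})
    return pd.DataFrame(rows)
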