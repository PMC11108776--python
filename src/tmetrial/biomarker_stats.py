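"""Group-association statistics for biomarker analyses.

Every statistic here is implemented in this module rather than delegated:
Mann–Whitney U (exact enumeration for small untied samples, tie-corrected
normal approximation otherwise), Fisher's exact test (minimum-likelihood
two-sided rule), the Pearson chi-square on 2x2 tables, 2x2 diagnostic
metrics, tertile dichotomization, pairwise-complete Pearson correlation
with average-linkage clustering, a logistic model fitted by iteratively
reweighted least squares, and the rank-formulation ROC AUC. The scientific
convention throughout is the trial's own: two-sided tests, no
multiple-comparison adjustment.

scipy / statsmodels / scikit-learn implementations of the same statistics
are used in the test-suite as independent cross-checks only.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TwoByTwo",
    "MannWhitneyResult",
    "mann_whitney",
    "fisher_exact",
    "chi_square",
    "diagnostics",
    "bottom_tertile_cutoff",
    "dichotomize",
    "pairwise_pearson",
    "correlation_cluster",
    "LogisticFit",
    "logistic_fit",
    "TmeLogisticModel",
    "RocResult",
    "roc_auc",
]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table; rows = biomarker high/low, columns = benefit/no-benefit."""

    a: int  # high & benefit
    b: int  # high & no benefit
    c: int  # low & benefit
    d: int  # low & no benefit

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# Rank machinery


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties sharing their midrank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_null_counts(m: int, n: int) -> np.ndarray:
    """Null distribution of the Mann–Whitney U statistic, by counting.

    ``counts[u]`` is the number of the C(m+n, m) equally likely rank
    assignments giving U = u for the size-``m`` group. U counts are the
    coefficients of the Gaussian binomial [m+n choose m]_q, built with the
    q-Pascal recurrence G(j, k) = G(j-1, k) + q^j G(j, k-1).
    """
    polys: list[np.ndarray] = [np.array([1.0])] * (m + 1)  # G(j, 0) = 1
    for _k in range(1, n + 1):
        new = [np.array([1.0])]
        for j in range(1, m + 1):
            a, b = new[j - 1], polys[j]
            c = np.zeros(max(len(a), j + len(b)))
            c[: len(a)] += a
            c[j : j + len(b)] += b
            new.append(c)
        polys = new
    counts = np.zeros(m * n + 1)
    counts[: len(polys[m])] = polys[m]
    return counts


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    pvalue: float
    method: str  # "exact" | "normal"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney test.

    Exact enumeration of the U null distribution when the smaller group has
    at most 8 observations and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mean = nx * ny / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and min(nx, ny) <= 8:
        m = min(nx, ny)
        u_small = u_x if nx <= ny else nx * ny - u_x
        counts = _u_null_counts(m, max(nx, ny))
        total = counts.sum()
        dev = abs(u_small - mean)
        us = np.arange(counts.size)
        p = float(counts[np.abs(us - mean) >= dev - 1e-9].sum() / total)
        return MannWhitneyResult(u_x, min(p, 1.0), "exact")

    n = nx + ny
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return MannWhitneyResult(u_x, 1.0, "normal")
    cc = 0.5 if u_x != mean else 0.0
    z = (abs(u_x - mean) - cc) / math.sqrt(var)
    p = math.erfc(max(z, 0.0) / math.sqrt(2.0))
    return MannWhitneyResult(u_x, min(p, 1.0), "normal")


# ---------------------------------------------------------------------------
# 2x2 tables


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(first cell = a) for fixed margins (row1, row2; col1)."""
    n = row1 + row2
    return (
        math.lgamma(row1 + 1) - math.lgamma(a + 1) - math.lgamma(row1 - a + 1)
        + math.lgamma(row2 + 1)
        - math.lgamma(col1 - a + 1)
        - math.lgamma(row2 - (col1 - a) + 1)
        - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
    )


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule.

    Sums the probabilities of every table with the observed margins whose
    point probability does not exceed the observed table's (up to a small
    relative tolerance guarding float round-off).
    """
    row1, row2 = t.a + t.b, t.c + t.d
    col1 = t.a + t.c
    if row1 == 0 or row2 == 0 or col1 == 0 or t.b + t.d == 0:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    log_p_obs = _log_hypergeom_pmf(t.a, row1, row2, col1)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(a, row1, row2, col1)
        if lp <= log_p_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def chi_square(t: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, two-sided upper-tail p."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if 0 in (r1, r2, c1, c2):
        logger.warning("chi-square on a margin-degenerate table; returning p = 1")
        return 0.0, 1.0
    det = abs(t.a * t.d - t.b * t.c)
    if yates:
        det = max(det - t.n / 2.0, 0.0)
    stat = t.n * det**2 / (r1 * r2 * c1 * c2)
    p = math.erfc(math.sqrt(stat / 2.0))  # chi2(1) upper tail
    return float(stat), min(float(p), 1.0)


def diagnostics(t: TwoByTwo) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV (percent) with biomarker-high as the
    positive test and benefit as the positive outcome; NaN where the
    denominator is zero."""

    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    return {
        "sensitivity": _pct(t.a, t.a + t.c),
        "specificity": _pct(t.d, t.b + t.d),
        "ppv": _pct(t.a, t.a + t.b),
        "npv": _pct(t.d, t.c + t.d),
    }


# ---------------------------------------------------------------------------
# Dichotomization


def bottom_tertile_cutoff(values: Sequence[float]) -> float:
    """The 33 1/3rd percentile by linear interpolation of order statistics.

    This is the rule used to dichotomize biomarkers (high iff value is
    strictly above the cutoff); the cutoff itself is data-derived.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 3:
        raise ValueError("need at least 3 non-missing values for a tertile cutoff")
    return float(np.quantile(vals, 1.0 / 3.0, method="linear"))


def dichotomize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """Boolean high/low split: high iff value > cutoff (NaN stays False)."""
    vals = np.asarray(values, dtype=float)
    high = vals > cutoff
    if high.all() or not high[~np.isnan(vals)].any():
        logger.warning("degenerate dichotomization: all values on one side of cutoff")
    return high


# ---------------------------------------------------------------------------
# Correlation and clustering


def pairwise_pearson(m: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Each pair uses the rows where both columns are observed; pairs with
    fewer than ``min_obs`` complete observations, or with a constant
    column, get NaN.
    """
    cols = list(m.columns)
    data = m.to_numpy(dtype=float)
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            mask = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            if mask.sum() < min_obs:
                continue
            xi, xj = data[mask, i], data[mask, j]
            xi = xi - xi.mean()
            xj = xj - xj.mean()
            denom = math.sqrt((xi**2).sum() * (xj**2).sum())
            if denom == 0:
                continue
            out[i, j] = out[j, i] = float((xi * xj).sum() / denom)
    return pd.DataFrame(out, index=cols, columns=cols)


def correlation_cluster(
    m: pd.DataFrame, min_obs: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix plus an average-linkage dendrogram order.

    Parameters are clustered on the dissimilarity 1 - r by agglomerative
    average linkage (unweighted pair-average over all cross-cluster pairs);
    the returned list is the left-to-right leaf order. Columns whose
    correlations are undefined (constant, or too few complete pairs) are
    excluded from clustering with a warning and appended at the end.
    """
    corr = pairwise_pearson(m, min_obs=min_obs)
    cols = list(corr.columns)
    # greedily drop the column with the most undefined pairs until the
    # remaining correlation submatrix is complete
    valid = list(cols)
    while len(valid) > 1:
        nan_counts = {
            c: int(corr.loc[c, [o for o in valid if o != c]].isna().sum())
            for c in valid
        }
        worst = max(valid, key=lambda c: nan_counts[c])
        if nan_counts[worst] == 0:
            break
        valid.remove(worst)
    dropped = [c for c in cols if c not in valid]
    if dropped:
        logger.warning("columns excluded from clustering (undefined r): %s", dropped)
    if len(valid) < 2:
        return corr, valid + dropped

    idx = {c: i for i, c in enumerate(valid)}
    dist = 1.0 - corr.loc[valid, valid].to_numpy()
    # active clusters: id -> (member leaf indices, ordered leaf list)
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(valid))}
    order: dict[int, list[int]] = {i: [i] for i in range(len(valid))}
    next_id = len(valid)
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ii, ci in enumerate(ids):
            for cj in ids[ii + 1 :]:
                d = float(
                    np.mean([dist[a, b] for a in clusters[ci] for b in clusters[cj]])
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, ci, cj)
        _, ci, cj = best
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        order[next_id] = order.pop(ci) + order.pop(cj)
        next_id += 1
    leaf_order = [valid[i] for i in order[next_id - 1]]
    return corr, leaf_order + dropped


# ---------------------------------------------------------------------------
# Logistic model (IRLS)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit. ``params[0]`` is the intercept."""

    params: np.ndarray
    se: np.ndarray
    fitted: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separated: bool


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 30.0,
) -> LogisticFit:
    """Fit logit P(y=1) = b0 + X b by iteratively reweighted least squares.

    Convergence when the largest coefficient change drops below ``tol``.
    Complete separation is detected as a diverging coefficient norm and
    reported in the ``separated`` flag instead of being silently returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 6:
        raise ValueError("need at least 6 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    Xd = np.column_stack([np.ones(n), X])
    k = Xd.shape[1]
    beta = np.zeros(k)
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(p * (1 - p), 1e-12, None)
        # Newton step: beta += (X' W X)^-1 X' (y - p)
        xtwx = Xd.T @ (Xd * w[:, None])
        grad = Xd.T @ (y - p)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(xtwx, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > separation_bound:
            separated = True
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xd @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(p * (1 - p), 1e-12, None)
    cov = np.linalg.pinv(Xd.T @ (Xd * w[:, None]))
    se = np.sqrt(np.diag(cov))
    eps = 1e-12
    ll = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    if separated:
        logger.warning("logistic fit: complete or quasi-complete separation detected")
    return LogisticFit(beta, se, p, ll, it, converged, separated)


class TmeLogisticModel:
    """scikit-learn-style two-covariate benefit classifier.

    A thin estimator wrapper over :func:`logistic_fit` so the biomarker
    model composes with sklearn pipelines and model selection. Fitted
    attributes: ``coef_``, ``intercept_``, ``classes_``, ``converged_``,
    ``separated_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    # minimal get_params/set_params for sklearn compatibility
    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "TmeLogisticModel":
        for key, value in params.items():
            if key not in ("tol", "max_iter"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "TmeLogisticModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("TmeLogisticModel requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        fit = logistic_fit(X, y01, tol=self.tol, max_iter=self.max_iter)
        self.fit_result_ = fit
        self.intercept_ = np.array([fit.params[0]])
        self.coef_ = fit.params[1:][None, :]
        self.converged_ = fit.converged
        self.separated_ = fit.separated
        self.n_features_in_ = self.coef_.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_[0] + X @ self.coef_[0]

    def predict_proba(self, X) -> np.ndarray:
        eta = np.clip(self.decision_function(X), -35, 35)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve and AUC.

    The AUC uses the rank (Mann–Whitney) formulation with tied scores
    counted 1/2; the curve is a threshold sweep over the distinct score
    values (one step per tied group), so trapezoidal integration of the
    returned points reproduces the rank AUC by construction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = _midranks(scores)
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # keep the last index of each tied-score group
    last = np.r_[np.flatnonzero(np.diff(sorted_scores) != 0), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return RocResult(fpr, tpr, auc)
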