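"""Shared statistical kernel.

Covariate-adjusted linear-model tests (ANOVA F for a three-level group
factor, t-test for a binary indicator), Benjamini-Hochberg adjustment,
exact 2x2 contingency tests with a hypergeometric-tail companion,
Stouffer signed-z meta-analysis, and a normal-approximation sample-size
calculation.  Everything here is pure in-memory computation on numpy
arrays; the batch variants vectorize a shared design matrix across many
response columns (one per aptamer), which is what makes genome-scale
per-aptamer testing cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "fit_anova_f",
    "fit_binary_adjusted",
    "batch_anova_f",
    "batch_binary_adjusted",
    "bh_adjust",
    "fisher_exact_2x2",
    "hypergeom_upper_tail",
    "stouffer_meta",
    "required_n_two_group",
]


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome.

    ``effect`` is on the model (log-RFU) scale: for the three-group
    F-test it is the centenarian-vs-pooled-younger adjusted difference,
    for the binary test the OLS coefficient on the indicator.
    """

    statistic: float
    p_value: float
    effect: float
    df: tuple
    #: adjusted (covariate-held-fixed) level means where applicable
    adjusted_means: dict | None = None


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be non-negative integers, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


# ---------------------------------------------------------------------------
# Linear-model tests (nested OLS)
# ---------------------------------------------------------------------------

def _design_with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    return np.hstack(cols)


def _check_rank(X: np.ndarray, label: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix ({label}): collinear columns")


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y regressed on X (via QR)."""
    Q, _ = np.linalg.qr(X)
    fitted_ss = np.sum((Q.T @ Y) ** 2, axis=0)
    total_ss = np.sum(Y**2, axis=0)
    return np.maximum(total_ss - fitted_ss, 0.0)


def batch_anova_f(
    Y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested-OLS F test of a multi-level group factor, per column of Y.

    Full model: intercept + covariates + group indicators; reduced model
    drops the group indicators.  Returns (F, p, effect) where effect is
    the adjusted mean of the first group level (sorted order) minus the
    adjusted mean of the remaining samples.

    Constant (zero-variance) columns get F = 0, p = 1 by convention so
    expressionless aptamers flow through the pipeline.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and len(group) != 1:
        Y = Y.T
    n = Y.shape[0]
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("group factor needs at least two levels")
    X_red = _design_with_intercept(covariates, n)
    # treatment-coded indicators, first level as reference
    ind = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    X_full = np.hstack([X_red, ind])
    _check_rank(X_full, "full model")
    k = X_full.shape[1]
    df1 = len(levels) - 1
    df2 = n - k
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    rss_full = _rss(Y, X_full)
    rss_red = _rss(Y, X_red)
    total_var = Y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_red - rss_full) / df1 / (rss_full / df2)
    # degenerate columns: constant response
    const = total_var <= 1e-30
    F = np.where(const, 0.0, F)
    F = np.where(np.isfinite(F), F, np.inf)
    p = sps.f.sf(F, df1, df2)
    p = np.where(const, 1.0, p)
    # adjusted effect: coefficients of the full model
    beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    # adjusted mean difference of level 0 vs average of other levels:
    # reference level has indicator coefs 0, others beta[-df1:]
    effect = -beta[-df1:].mean(axis=0)
    return F, p, effect


def fit_anova_f(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> TestResult:
    """Covariate-adjusted ANOVA F test for a single response vector.

    The p-value comes from the F distribution with (levels-1, n-k)
    degrees of freedom; adjusted group means are evaluated at the mean
    of the covariate columns.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains missing/non-finite values")
    n = len(y)
    group = np.asarray(group)
    levels = np.unique(group)
    F, p, effect = batch_anova_f(y[:, None], group, covariates)
    X_red = _design_with_intercept(covariates, n)
    ind = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    X_full = np.hstack([X_red, ind])
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    covmeans = X_red.mean(axis=0)
    base = float(covmeans @ beta[: X_red.shape[1]])
    adj = {str(levels[0]): base}
    for i, g in enumerate(levels[1:]):
        adj[str(g)] = base + float(beta[X_red.shape[1] + i])
    df2 = n - X_full.shape[1]
    return TestResult(float(F[0]), float(p[0]), float(effect[0]),
                      (len(levels) - 1, df2), adj)


def batch_binary_adjusted(
    Y: np.ndarray,
    indicator: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS coefficient on a 0/1 indicator with two-sided t test, per column.

    Returns (t, p, coef).  The indicator enters the design last; its
    coefficient is the adjusted log-scale effect of class 1 vs class 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    indicator = np.asarray(indicator, dtype=float)
    if Y.shape[0] == 1 and len(indicator) != 1:
        Y = Y.T
    n = Y.shape[0]
    if len(np.unique(indicator)) < 2:
        raise ValueError("indicator has a single level; both classes required")
    X = np.hstack([_design_with_intercept(covariates, n), indicator[:, None]])
    _check_rank(X, "binary model")
    k = X.shape[1]
    df = n - k
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[-1, -1], 0.0))
    coef = beta[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.where(np.abs(coef) > 0, np.inf, 0.0))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    const = Y.var(axis=0) <= 1e-30
    t = np.where(const, 0.0, t)
    p = np.where(const, 1.0, p)
    return t, p, coef


def fit_binary_adjusted(
    y: np.ndarray,
    indicator: np.ndarray,
    covariates: np.ndarray | None = None,
) -> TestResult:
    """Adjusted two-class comparison for a single response vector."""
    y = np.asarray(y, dtype=float)
    t, p, coef = batch_binary_adjusted(y[:, None], indicator, covariates)
    n = len(y)
    k = _design_with_intercept(covariates, n).shape[1] + 1
    return TestResult(float(t[0]), float(p[0]), float(coef[0]), (n - k,))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Exact contingency tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[TestResult, float]:
    """Two-sided Fisher exact test and sample odds ratio.

    Two-sidedness follows the minimum-likelihood summation convention:
    the p-value sums hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed that of the
    observed table (ties at a 1+1e-7 relative tolerance).  The odds
    ratio is the sample ad/bc, with infinity when bc = 0.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.asarray(table).ravel().tolist())
    arr = table.as_array()
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = np.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else np.nan
    return TestResult(float(odds) if np.isfinite(odds) else np.inf,
                      float(p), float(np.log(odds)) if 0 < odds < np.inf else np.nan,
                      (1,)), odds


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), summed in log space.

    The one-sided companion to :func:`fisher_exact_2x2` and the kernel
    of over-representation tests: the chance of drawing at least ``x``
    marked items in ``n`` draws without replacement from a universe of
    ``N`` containing ``K`` marked.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    hi = min(n, K)
    if not (0 <= x <= hi):
        raise ValueError(f"x={x} outside support [0, {hi}]")
    support = np.arange(x, hi + 1)
    logp = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


# ---------------------------------------------------------------------------
# Meta-analysis and power
# ---------------------------------------------------------------------------

def stouffer_meta(z: np.ndarray, w: np.ndarray) -> TestResult:
    """Weighted Stouffer combination of signed z-scores.

    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)); two-sided p from N(0, 1).
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.size == 0:
        raise ValueError("no z-scores to combine")
    if np.any(~np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    zm = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p = float(2.0 * sps.norm.sf(abs(zm)))
    return TestResult(zm, p, zm, (np.inf,))


def required_n_two_group(effect_d: float, alpha: float, power: float) -> int:
    """Total two-group sample size by the normal approximation.

    n_total = 4 ((z_{1-alpha/2} + z_{power}) / d)^2, rounded up.
    """
    if effect_d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    za = sps.norm.ppf(1 - alpha / 2)
    zb = sps.norm.ppf(power)
    return int(np.ceil(4.0 * ((za + zb) / effect_d) ** 2))
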