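"""Inferential toolkit: Welch t, Cohen's d with noncentral-t confidence
intervals, TOST equivalence tests, power for the t-test and for TOST,
paired comparisons, Pearson correlation, OLS, and fixed-effects
meta-analysis of standardized mean differences.

All two-sample procedures accept either raw samples or printed group
summaries (n, M, sd), because published tables are a first-class input.
Sign convention throughout: d = (group1 - group2) / s_pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import brentq

ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and sample (n-1 denominator) standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(len(x), float(x.mean()), float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    alternative: str


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class TostResult:
    bound_d: float
    t_lower: float
    t_upper: float
    df: float
    p_tost: float
    equivalent: bool
    alpha: float


@dataclass(frozen=True)
class MetaResult:
    d_pooled: float
    ci_low: float
    ci_high: float
    weights: tuple


def _p_from_t(t: float, df: float, alternative: str) -> float:
    if alternative == "two_sided":
        return 2.0 * sps.t.sf(abs(t), df)
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def welch_from_summaries(
    g1: GroupSummary, g2: GroupSummary, alternative: str = "two_sided", shift: float = 0.0
) -> TestResult:
    """Welch's t-test of mean1 - mean2 = shift with Welch-Satterthwaite df."""
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    se = math.sqrt(v1 + v2)
    if se == 0.0:
        raise ValueError("both groups have zero variance; t is undefined")
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    t = (g1.mean - g2.mean - shift) / se
    return TestResult(t, df, _p_from_t(t, df, alternative), alternative)


def welch_t(x, y, alternative: str = "two_sided") -> TestResult:
    return welch_from_summaries(
        GroupSummary.from_sample(x), GroupSummary.from_sample(y), alternative
    )


def pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    return math.sqrt(
        ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    )


def _nct_ci(t_obs: float, df: float, level: float) -> tuple[float, float]:
    """Invert the noncentral-t CDF in the noncentrality parameter: the CI is
    the set of ncp values under which t_obs is not in the outer tails."""
    alpha = (1.0 - level) / 2.0

    def cdf(ncp: float) -> float:
        v = sps.nct.cdf(t_obs, df, ncp)
        if math.isnan(v):  # deep-tail underflow in scipy: use the limit
            return 0.0 if ncp > t_obs else 1.0
        return float(v)

    def lo_eq(ncp):  # t_obs at the upper tail => lower bound
        return cdf(ncp) - (1.0 - alpha)

    def hi_eq(ncp):
        return cdf(ncp) - alpha

    span = abs(t_obs) + 10.0 + 5.0 * math.sqrt(1.0 + t_obs**2 / max(df, 1.0))
    lo = brentq(lo_eq, t_obs - span, t_obs + span, xtol=1e-10)
    hi = brentq(hi_eq, t_obs - span, t_obs + span, xtol=1e-10)
    return lo, hi


def cohens_d_from_summaries(
    g1: GroupSummary, g2: GroupSummary, level: float = 0.95
) -> EffectSize:
    """Cohen's d = (mean1 - mean2)/s_pooled with a noncentral-t CI.

    The CI inverts the noncentral-t distribution of t = d * sqrt(n1*n2/N)
    on df = n1 + n2 - 2 (pooled d is reported even alongside Welch tests,
    the conventional pairing).
    """
    sp = pooled_sd(g1, g2)
    if sp == 0.0:
        raise ValueError("zero pooled sd; d is undefined")
    d = (g1.mean - g2.mean) / sp
    scale = math.sqrt(g1.n * g2.n / (g1.n + g2.n))
    ncp_lo, ncp_hi = _nct_ci(d * scale, g1.n + g2.n - 2, level)
    return EffectSize(d, ncp_lo / scale, ncp_hi / scale, level)


def cohens_d(x, y, level: float = 0.95) -> EffectSize:
    return cohens_d_from_summaries(
        GroupSummary.from_sample(x), GroupSummary.from_sample(y), level
    )


def tost_from_summaries(
    g1: GroupSummary, g2: GroupSummary, bound_d: float = 0.36, alpha: float = 0.05
) -> TostResult:
    """Two one-sided Welch tests against raw bounds +-bound_d * s_pooled.

    Rejecting both one-sided nulls (p_tost = max of the two p's < alpha)
    declares the groups equivalent within the d bounds.
    """
    if bound_d <= 0:
        raise ValueError("bound_d must be positive")
    delta = bound_d * pooled_sd(g1, g2)
    lower = welch_from_summaries(g1, g2, "greater", shift=-delta)
    upper = welch_from_summaries(g1, g2, "less", shift=delta)
    p_tost = max(lower.p, upper.p)
    return TostResult(
        bound_d, lower.statistic, upper.statistic, lower.df, p_tost, p_tost < alpha, alpha
    )


def tost(x, y, bound_d: float = 0.36, alpha: float = 0.05) -> TostResult:
    return tost_from_summaries(
        GroupSummary.from_sample(x), GroupSummary.from_sample(y), bound_d, alpha
    )


def power_t_at(n_per_group: int, d: float, alpha: float = 0.05, alternative: str = "greater") -> float:
    """Power of a two-sample t-test at n per group against true effect d,
    from the noncentral t with df = 2n - 2 and ncp = d * sqrt(n/2)."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    if alternative == "two_sided":
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tc, df, ncp))


def power_t(
    d: float,
    alpha: float = 0.05,
    target_power: float = 0.95,
    alternative: str = "greater",
    n_max: int = 1_000_000,
) -> int:
    """Smallest integer n per group with power >= target_power against d."""
    if d <= 0 or not (0 < alpha < 1) or not (0 < target_power < 1):
        raise ValueError("need d > 0 and alpha, target_power in (0, 1)")
    # bracket by doubling, then binary search on the monotone power curve
    n = 2
    while power_t_at(n, d, alpha, alternative) < target_power:
        n *= 2
        if n > n_max:
            raise ValueError("target power unreachable within n_max")
    lo, hi = max(2, n // 2), n
    while lo < hi:
        mid = (lo + hi) // 2
        if power_t_at(mid, d, alpha, alternative) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def power_tost(
    n_per_group: int, bound_d: float = 0.36, alpha: float = 0.05, true_d: float = 0.0
) -> float:
    """Analytic power of the TOST procedure: probability that the t statistic
    falls inside (t_crit - delta_b, delta_b - t_crit) where delta_b is the
    equivalence bound in noncentrality units, under the true effect."""
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    tc = sps.t.ppf(1.0 - alpha, df)
    db = bound_d * math.sqrt(n_per_group / 2.0)
    ncp = true_d * math.sqrt(n_per_group / 2.0)
    power = sps.nct.cdf(db - tc, df, ncp) - sps.nct.cdf(tc - db, df, ncp)
    return float(max(0.0, power))


def paired_t(diffs, alternative: str = "two_sided") -> TestResult:
    """One-sample t on paired differences (df = n - 1)."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 non-missing differences")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero sd of differences; t is undefined")
    t = diffs.mean() / (sd / math.sqrt(n))
    return TestResult(float(t), n - 1, _p_from_t(t, n - 1, alternative), alternative)


def paired_d(diffs, level: float = 0.95) -> EffectSize:
    """d_z = mean(diff)/sd(diff) with a noncentral-t CI (ncp scale sqrt(n))."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 non-missing differences")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero sd of differences; d is undefined")
    d = float(diffs.mean() / sd)
    scale = math.sqrt(n)
    ncp_lo, ncp_hi = _nct_ci(d * scale, n - 1, level)
    return EffectSize(d, ncp_lo / scale, ncp_hi / scale, level)


def pearson_r(x, y, level: float = 0.95):
    """Pearson correlation with a Fisher-z confidence interval.

    Returns (r, (ci_low, ci_high), p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    r, p = sps.pearsonr(x, y)
    z = math.atanh(r)
    zc = sps.norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = zc / math.sqrt(n - 3)
    return float(r), (math.tanh(z - half), math.tanh(z + half)), float(p)


def ols(y, X, names: list[str] | None = None):
    """OLS of y on X (intercept added) with classical standard errors.

    Returns a statsmodels results object; raises on rank deficiency, naming
    the offending column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{i+1}" for i in range(X.shape[1])]
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"column {names[j]!r} is constant; model is rank deficient")
    import pandas as pd

    design = sm.add_constant(pd.DataFrame(X, columns=list(names)))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def meta_fixed(studies: list[tuple[float, int, int]]) -> MetaResult:
    """Fixed-effects (inverse-variance) pooling of standardized mean
    differences; var(d_i) = (n1+n2)/(n1*n2) + d^2/(2*(n1+n2))."""
    if not studies:
        raise ValueError("need at least one study")
    ds, ws = [], []
    for d, n1, n2 in studies:
        if n1 <= 0 or n2 <= 0:
            raise ValueError("group sizes must be positive")
        var = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
        ds.append(d)
        ws.append(1.0 / var)
    ds, ws = np.array(ds), np.array(ws)
    pooled = float((ws * ds).sum() / ws.sum())
    se = 1.0 / math.sqrt(ws.sum())
    zc = sps.norm.ppf(0.975)
    return MetaResult(pooled, pooled - zc * se, pooled + zc * se, tuple(ws))


def holm(pvalues):
    """Holm step-down adjusted p-values (for the exploratory battery)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvalues, method="holm")[1]
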