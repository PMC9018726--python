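"""Power-law scaling fits and the nonparametric group comparisons.

The channel-length/area relation L = a * Area**b is fit by OLS on natural
logs. Group differences in the scaling relation are tested with the nested
F-test between a pooled log-log line and the full model with group-specific
intercept and slope (df = 2, n - 4). Metric comparisons between wetland
types use the two-sided two-sample Wilcoxon rank-sum test, exact by
enumeration for small tie-free samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats

EXACT_LIMIT = 20  # exact Wilcoxon enumeration up to this combined n


@dataclass
class PowerLawFit:
    a: float
    b: float
    n: int
    F: float
    df1: int
    df2: int
    r2: float
    residual_log_sd: float

    def predict(self, area):
        return self.a * np.asarray(area, dtype=float) ** self.b


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    exact: bool = False


def fit_power_law(areas, lengths) -> PowerLawFit:
    """OLS of ln(length) on ln(area): a = exp(intercept), b = slope.

    F is the regression F-statistic on (1, n - 2) degrees of freedom.
    """
    x = np.asarray(areas, dtype=float)
    y = np.asarray(lengths, dtype=float)
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if len(bad):
        raise ValueError(f"non-positive values at indices {bad.tolist()}")
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need >= 3 paired positive observations")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    fitted = intercept + slope * lx
    sse = float(np.sum((ly - fitted) ** 2))
    ssr = float(np.sum((fitted - ly.mean()) ** 2))
    sst = ssr + sse
    df2 = n - 2
    mse = sse / df2
    f_stat = (ssr / 1.0) / mse if mse > 0 else np.inf
    r2 = ssr / sst if sst > 0 else 1.0
    return PowerLawFit(
        a=float(np.exp(intercept)),
        b=float(slope),
        n=n,
        F=float(f_stat),
        df1=1,
        df2=df2,
        r2=float(r2),
        residual_log_sd=float(sqrt(mse)) if mse > 0 else 0.0,
    )


def compare_power_laws(areas, lengths, groups) -> GroupComparison:
    """Nested F-test: pooled log-log line vs group-specific intercept+slope.

    ``groups`` holds exactly two distinct labels; the reduction in residual
    sum of squares is tested on (2, n - 4) degrees of freedom.
    """
    x = np.asarray(areas, dtype=float)
    y = np.asarray(lengths, dtype=float)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    for lab in labels:
        if np.sum(g == lab) < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("areas and lengths must be positive")

    lx, ly = np.log(x), np.log(y)
    n = len(lx)

    def rss_line(xs, ys):
        slope, intercept = np.polyfit(xs, ys, 1)
        return float(np.sum((ys - intercept - slope * xs) ** 2))

    rss_pooled = rss_line(lx, ly)
    rss_full = sum(rss_line(lx[g == lab], ly[g == lab]) for lab in labels)
    df_num, df_den = 2, n - 4
    if rss_full <= 0:
        f_stat = 0.0 if rss_pooled - rss_full <= 1e-12 * max(rss_pooled, 1.0) else np.inf
    else:
        f_stat = ((rss_pooled - rss_full) / df_num) / (rss_full / df_den)
        f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
    return GroupComparison(
        test_name=f"nested F ({df_num}, {df_den})",
        statistic=float(f_stat),
        p_value=p,
        n1=int(np.sum(g == labels[0])),
        n2=int(np.sum(g == labels[1])),
        exact=False,
    )


def _exact_rank_sum_p(w: float, n1: int, n2: int) -> float:
    """Two-sided exact p for the rank-sum W of the first sample, by full
    enumeration of all C(n1+n2, n1) rank assignments."""
    total = comb(n1 + n2, n1)
    n_le = n_ge = 0
    for ranks in combinations(range(1, n1 + n2 + 1), n1):
        s = sum(ranks)
        if s <= w + 1e-12:
            n_le += 1
        if s >= w - 1e-12:
            n_ge += 1
    p = 2.0 * min(n_le, n_ge) / total
    return min(p, 1.0)


def wilcoxon_rank_sum(x, y) -> GroupComparison:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Exact by enumeration when n1 + n2 <= 20 and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    The statistic is the rank sum W of ``x`` in the combined sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(np.sum(ranks[:n1]))
    has_ties = len(np.unique(combined)) < n1 + n2

    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        p = _exact_rank_sum_p(w, n1, n2)
        return GroupComparison("wilcoxon rank-sum (exact)", w, p, n1, n2, exact=True)

    mean_w = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w <= 0:
        return GroupComparison("wilcoxon rank-sum (approx)", w, 1.0, n1, n2, exact=False)
    diff = w - mean_w
    cc = 0.5 if diff != 0 else 0.0  # continuity correction toward the mean
    z = (diff - np.sign(diff) * cc) / sqrt(var_w)
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    return GroupComparison("wilcoxon rank-sum (approx)", w, p, n1, n2, exact=False)


def shapiro_wilk(x) -> GroupComparison:
    """Shapiro-Wilk normality test (gate before the Wilcoxon comparison).

    Constant input raises: the statistic is undefined without variance.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return GroupComparison("shapiro-wilk", float(w), float(p), n, 0, exact=False)
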