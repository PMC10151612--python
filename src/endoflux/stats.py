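"""Statistical summaries used by the surveys, implemented from their
classical definitions so the statistical surface of the package is itself
testable: a paired two-sided Wilcoxon signed-rank test and one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import f as f_dist

#: Largest sample size for which the signed-rank null is enumerated exactly.
EXACT_SIGNRANK_N = 25


@dataclass
class SignRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    n: int            # nonzero differences used
    p_value: float
    exact: bool


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False  # within-group SS zero with nonzero between-group SS


def wilcoxon_signed_rank(differences: Sequence[float]) -> SignRankResult:
    """Two-sided paired sign-rank test on a sample of differences.

    Zero differences are dropped; ties in |d| get average ranks.  The null
    distribution of ``W+`` (each rank signed positive with probability 1/2)
    is enumerated exactly by dynamic programming for n <= 25 and approximated
    by a normal with tie correction above.
    """
    d = np.asarray([x for x in differences if x != 0.0], dtype=float)
    n = len(d)
    if n == 0:
        return SignRankResult(statistic=0.0, n=0, p_value=1.0, exact=True)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    sorted_abs = np.abs(d)[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_SIGNRANK_N:
        # distribution of 2*W+ over the 2^n equiprobable sign assignments
        steps = np.rint(2 * ranks).astype(int)
        total = steps.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for s in steps:
            shifted = np.zeros_like(dist)
            shifted[s:] = dist[: len(dist) - s]
            dist = dist + shifted
        dist /= dist.sum()
        w2 = int(round(2 * w_plus))
        p_low = dist[: w2 + 1].sum()
        p_high = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return SignRankResult(statistic=w_plus, n=n, p_value=float(p), exact=True)

    mean = n * (n + 1) / 4.0
    # variance with tie correction: sum over tie groups of (t^3 - t)/48
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return SignRankResult(statistic=w_plus, n=n, p_value=1.0, exact=False)
    z = (w_plus - mean) / math.sqrt(var)
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return SignRankResult(statistic=w_plus, n=n, p_value=p, exact=False)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from between/within sums of squares.

    A degenerate case with zero within-group variance but distinct group
    means is reported with an infinite F and a zero p-value, flagged.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    k = len(arrays)
    if k < 2:
        raise ValueError("one_way_anova requires at least two groups of size >= 2")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    n_total = len(all_values)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within)
        return AnovaResult(math.inf, 0.0, df_between, df_within, degenerate=True)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(f_dist.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), p, df_between, df_within)
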