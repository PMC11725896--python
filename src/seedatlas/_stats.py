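"""Shared statistical primitives.

Small, heavily-reused pieces: Benjamini-Hochberg adjustment, the two-sided
rank-sum test (exact by enumeration for small pooled samples, normal
approximation with tie correction otherwise), and the hypergeometric
upper-tail enrichment test with a Haldane-corrected odds ratio.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

# pooled-sample-size cutoff below which the rank-sum test enumerates all splits
EXACT_RANKSUM_MAX_N = 14


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    For pooled n <= EXACT_RANKSUM_MAX_N the null distribution of the
    rank-sum statistic is enumerated over all C(n, n_x) group assignments
    (midranks, so ties are handled exactly) and the two-sided p is the
    doubled smaller tail, capped at 1.  Larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    n = n1 + n2
    if n <= EXACT_RANKSUM_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        ws = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n1)])
        lo = np.mean(ws <= w_obs + 1e-9)
        hi = np.mean(ws >= w_obs - 1e-9)
        return float(min(1.0, 2.0 * min(lo, hi)))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def rank_sum_test_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for (genes x cells) blocks.

    Uses the same exact/asymptotic switch as :func:`rank_sum_test`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[1] + y.shape[1] <= EXACT_RANKSUM_MAX_N:
        return np.array([rank_sum_test(xi, yi) for xi, yi in zip(x, y)])
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", axis=1)
    return np.asarray(res.pvalue, dtype=float)


def hypergeom_upper_tail(overlap: int, n_a: int, n_b: int, background: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, n_b successes, n_a draws)."""
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, background, n_b, n_a))


def odds_ratio_2x2(overlap: int, n_a: int, n_b: int, background: int) -> float:
    """Odds ratio of the overlap 2x2 table, Haldane +0.5 when any cell is zero."""
    a = overlap
    b = n_a - overlap
    c = n_b - overlap
    d = background - n_a - n_b + overlap
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 table")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))
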