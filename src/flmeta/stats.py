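"""Exact small-sample tests shared by the propensity and covariate analyses.

Two tests are implemented here rather than taken from a library:

* the two-sided Fisher exact test, computed with exact integer arithmetic
  under the "sum of tables at most as probable as the observed one"
  convention, so its tie handling is deterministic and free of floating-point
  inclusion thresholds;
* the Wilcoxon rank-sum (Mann-Whitney) test, whose exact branch computes the
  full permutation null of the rank sum by dynamic programming over the
  (tie-averaged) pooled ranks — mathematically identical to enumerating all
  C(n+m, n) group assignments, and valid under ties.

The asymptotic Wilcoxon branch delegates to scipy (normal approximation with
tie and continuity correction).  Benjamini-Hochberg adjustment delegates to
statsmodels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: exact Wilcoxon branch is used when both groups are at most this large
EXACT_WILCOXON_MAX_GROUP = 25


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums the (conditional hypergeometric) probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's, with ties resolved exactly in integer arithmetic.  The
    odds ratio is the sample cross-product a*d / (b*c); it is ``inf`` when
    b*c = 0 < a*d and ``nan`` when both products are 0 (a continuity-corrected
    estimate would be needed for a finite value in those cases).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    if a * d > 0 and b * c == 0:
        odds = float("inf")
    elif b * c == 0:
        odds = float("nan")
    else:
        odds = (a * d) / (b * c)

    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return FisherResult(((a, b), (c, d)), odds, 1.0)

    # unnormalised probability of each table with these margins (integer)
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)]
    observed = weights[a - k_min]
    numerator = sum(w for w in weights if w <= observed)
    p = numerator / comb(n, c1)
    return FisherResult(((a, b), (c, d)), odds, min(1.0, p))


@dataclass
class WilcoxonResult:
    statistic: float          # rank sum of the first group
    p_value: float
    method: str               # "exact" or "asymptotic"
    n1: int
    n2: int


def _exact_rank_sum_p(r2: np.ndarray, n1: int, w2: int) -> float:
    """Exact two-sided p for the rank sum via subset-sum DP.

    ``r2`` holds the pooled ranks doubled (integers even under tie
    averaging); ``w2`` is the doubled observed rank sum of group 1.  The
    permutation distribution of the rank sum is symmetric about
    n1*(N+1)/2 because reversing the rank order maps the pooled rank multiset
    onto itself, so "two-sided" = probability of a deviation from the mean at
    least as large as observed.
    """
    n = len(r2)
    total2 = int(r2.sum())          # == n*(n+1)
    # dp[j, s] = number of j-subsets of the ranks processed so far with sum s
    dp = np.zeros((n1 + 1, total2 + 1))
    dp[0, 0] = 1.0
    for i, r in enumerate(r2):
        jmax = min(i + 1, n1)
        for j in range(jmax, 0, -1):
            dp[j, r:] += dp[j - 1, : total2 + 1 - r]
    dist = dp[n1]
    mu2 = n1 * (n + 1)
    support = np.arange(total2 + 1)
    extreme = np.abs(support - mu2) >= abs(w2 - mu2) - 1e-9
    return float(dist[extreme].sum() / comb(n, n1))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    ``method`` is ``"exact"``, ``"asymptotic"`` or ``"auto"`` (exact when
    both groups have at most :data:`EXACT_WILCOXON_MAX_GROUP` observations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled, method="average")
    w = float(ranks[:n1].sum())

    if method == "auto":
        method = ("exact" if max(n1, n2) <= EXACT_WILCOXON_MAX_GROUP
                  else "asymptotic")
    if method == "exact":
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        w2 = int(round(2.0 * w))
        p = _exact_rank_sum_p(r2, n1, w2)
    elif method == "asymptotic":
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(statistic=w, p_value=min(1.0, p), method=method,
                          n1=n1, n2=n2)


@dataclass
class GroupComparisonResult:
    """Summary of a two-group comparison (means/SDs/medians + Wilcoxon p)."""

    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    median1: float
    median2: float
    p_value: float
    method: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "group": [self.group1, self.group2],
            "n": [self.n1, self.n2],
            "mean": [self.mean1, self.mean2],
            "sd": [self.sd1, self.sd2],
            "median": [self.median1, self.median2],
            "wilcoxon_p": [self.p_value] * 2,
            "method": [self.method] * 2,
        })


def compare_groups(values1, values2, group1: str, group2: str,
                   method: str = "auto") -> GroupComparisonResult:
    """Two-group comparison used by every Table-1-style analysis."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError(
            f"group {'1' if len(v1) == 0 else '2'} "
            f"({group1 if len(v1) == 0 else group2}) is empty")
    res = wilcoxon_rank_sum(v1, v2, method=method)
    return GroupComparisonResult(
        group1=group1, group2=group2, n1=len(v1), n2=len(v2),
        mean1=float(v1.mean()), mean2=float(v2.mean()),
        sd1=float(v1.std(ddof=1)) if len(v1) > 1 else 0.0,
        sd2=float(v2.std(ddof=1)) if len(v2) > 1 else 0.0,
        median1=float(np.median(v1)), median2=float(np.median(v2)),
        p_value=res.p_value, method=res.method)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
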