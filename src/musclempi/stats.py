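"""Nonparametric test battery: signed-rank, Friedman, Spearman, Kruskal-Wallis.

Conventions match the R reporting style common in clinical papers: the
signed-rank statistic V is the sum of ranks of the positive differences
(zero differences dropped, mid-ranks for ties), Friedman reports a
chi-squared statistic with k-1 degrees of freedom, and Kruskal-Wallis
post-hoc pairwise rank tests carry a Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    test: str
    statistic_name: str
    statistic: float
    p_value: float
    n: int
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired signed-rank test reporting V = sum of positive-difference ranks.

    Differences are ``x - y``; zero differences are dropped (the original
    treatment, and the hot path for clinical scores that do not change
    between visits).  The p-value is exact for n <= 25 without ties, and a
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; signed-rank test is degenerate")
        return TestResult("wilcoxon_signed_rank", "V", 0.0, 1.0, 0)
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", method=method, alternative="two-sided")
    return TestResult("wilcoxon_signed_rank", "V", v, float(res.pvalue), n)


def friedman(matrix) -> TestResult:
    """Friedman chi-squared test on a subjects x conditions matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 subjects")
    k = m.shape[1]
    if k < 3:
        raise ValueError(
            "Friedman requires >= 3 conditions; use wilcoxon_signed_rank for 2"
        )
    if np.all(m == m[:, :1]):  # every subject identical across conditions
        return TestResult("friedman", "F", 0.0, 1.0, m.shape[0], df=k - 1)
    stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(k)))
    return TestResult("friedman", "F", float(stat), float(p), m.shape[0], df=k - 1)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", "rho", float(rho), float(p), x.size)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * n_comparisons)."""
    return min(1.0, p * n_comparisons)


def kruskal_with_posthoc(groups, labels=None):
    """Kruskal-Wallis across groups, then pairwise rank-sum tests.

    Returns ``(TestResult, posthoc)`` where posthoc is a list of dicts with
    the pair, the rank-sum U statistic, the raw p and the Bonferroni-
    adjusted p over all pairwise comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        omnibus = TestResult(
            "kruskal_wallis", "chi2", 0.0, 1.0, pooled.size, df=len(groups) - 1
        )
    else:
        stat, p = sps.kruskal(*groups)
        omnibus = TestResult(
            "kruskal_wallis", "chi2", float(stat), float(p), pooled.size,
            df=len(groups) - 1,
        )
    pairs = [
        (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    posthoc = []
    for i, j in pairs:
        if np.unique(np.concatenate([groups[i], groups[j]])).size == 1:
            u, praw = float(groups[i].size * groups[j].size / 2), 1.0
        else:
            res = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            u, praw = float(res.statistic), float(res.pvalue)
        posthoc.append(
            {
                "pair": (labels[i], labels[j]),
                "U": u,
                "p_raw": praw,
                "p_bonferroni": bonferroni(praw, len(pairs)),
            }
        )
    return omnibus, posthoc
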