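"""Assemblage composition statistics.

Sex ratios, sex-by-period contingency tests, and total-length comparisons
for the abundant species of a survey: chi-square goodness of fit against a
1:1 sex ratio (no continuity correction — the published worked values are
uncorrected), Pearson chi-square across years/quarters, Welch two-sample
t-tests on lengths, Kruskal-Wallis rank-sum tests with tie correction, and
the post-hoc multiple comparison of mean ranks with a Bonferroni-style
k(k-1) divisor on alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from zicpue.errors import ReconstructionError, UndefinedTestError

__all__ = [
    "TestResult",
    "PosthocResult",
    "sex_ratio_gof",
    "reconstruct_counts",
    "sex_by_period_test",
    "length_ttest",
    "kruskal_wallis",
    "kw_posthoc",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    method: str


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise mean-rank comparisons after a Kruskal-Wallis test."""

    pairs: list[tuple]  # (group_i, group_j, diff_obs, diff_crit, significant)

    def significant_pairs(self) -> list[tuple]:
        return [(a, b) for a, b, _, _, sig in self.pairs if sig]


def sex_ratio_gof(males: int, females: int) -> TestResult:
    """Chi-square goodness of fit against a 1:1 sex ratio (uncorrected)."""
    if males + females < 1:
        raise UndefinedTestError("no sexed individuals")
    e = (males + females) / 2.0
    chi2 = (males - e) ** 2 / e + (females - e) ** 2 / e
    return TestResult(
        statistic=float(chi2),
        df=1,
        p=float(stats.chi2.sf(chi2, df=1)),
        method="chi-square goodness of fit vs 1:1",
    )


def reconstruct_counts(
    ratio: float, n_sexed: int, decimals: int = 2
) -> tuple[int, int]:
    """Recover the unique integer (males, females) split behind a rounded
    male:female ratio.

    Searches every split m + f = n_sexed with m, f >= 1 and keeps those
    whose ratio rounds back to the printed value; errors when zero or
    several splits qualify.
    """
    if ratio <= 0:
        raise ReconstructionError("ratio must be positive")
    if n_sexed < 2:
        raise ReconstructionError("need at least 2 sexed individuals")
    hits = [
        (m, n_sexed - m)
        for m in range(1, n_sexed)
        if round(m / (n_sexed - m), decimals) == round(ratio, decimals)
    ]
    if len(hits) != 1:
        raise ReconstructionError(
            f"ratio {ratio}:{1} of {n_sexed} sexed admits {len(hits)} integer "
            f"splits: {hits}"
        )
    return hits[0]


def sex_by_period_test(counts: np.ndarray) -> TestResult:
    """Pearson chi-square for a 2 x k sex-by-period table (df = k - 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise UndefinedTestError("need a 2 x k table with k >= 2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise UndefinedTestError("degenerate table: zero margin")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(
        statistic=float(chi2),
        df=int(df),
        p=float(p),
        method="Pearson chi-square (sex x period)",
    )


def length_ttest(a, b) -> TestResult:
    """Welch two-sample t-test on total lengths (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        raise UndefinedTestError("zero variance in both groups with equal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        method="Welch two-sample t-test",
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank-sum test with tie correction (chi2, df = k - 1)."""
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in cleaned if g.size > 0]
    if len(nonempty) < len(cleaned):
        warnings.warn("empty group(s) dropped from Kruskal-Wallis test", UserWarning)
    if len(nonempty) < 2:
        raise UndefinedTestError("need at least 2 non-empty groups")
    pooled = np.concatenate(nonempty)
    if np.ptp(pooled) == 0:
        # all observations tied: H = 0 by convention
        return TestResult(0.0, len(nonempty) - 1, 1.0, "Kruskal-Wallis rank sum")
    h, p = stats.kruskal(*nonempty)
    return TestResult(
        statistic=float(h),
        df=len(nonempty) - 1,
        p=float(p),
        method="Kruskal-Wallis rank sum",
    )


def kw_posthoc(groups, alpha: float = 0.05, labels=None) -> PosthocResult:
    """Post-hoc multiple comparison of mean ranks.

    For groups i, j the observed difference in mean ranks is compared to

        diff_crit = z_{1 - alpha / (k (k-1))} *
                    sqrt( N (N+1) / 12 * (1/n_i + 1/n_j) )

    and a pair is significant when diff_obs > diff_crit.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups if np.asarray(g).size > 0]
    k = len(cleaned)
    if k < 2:
        raise UndefinedTestError("need at least 2 non-empty groups")
    if labels is None:
        labels = list(range(k))
    sizes = np.array([g.size for g in cleaned], dtype=float)
    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in cleaned:
        mean_ranks.append(ranks[start: start + g.size].mean())
        start += g.size
    z_crit = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff_obs = abs(mean_ranks[i] - mean_ranks[j])
            diff_crit = z_crit * np.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            pairs.append(
                (labels[i], labels[j], float(diff_obs), float(diff_crit),
                 bool(diff_obs > diff_crit))
            )
    return PosthocResult(pairs=pairs)
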