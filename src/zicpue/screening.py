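"""Covariate correlation screening.

Before multi-covariate modeling, every pair of continuous covariates is
screened: Pearson's r with a Student-t test on n - 2 df and a Fisher-Z
95% confidence interval, plus Spearman's rank correlation s.  A pair is
flagged "problematic" — and its members are never used together in one
model — when all three of the following hold (threshold 0.3):

    i)   the null hypothesis rho = 0 is rejected (p < 0.05),
    ii)  max(|CI_low|, |CI_high|) >= 0.3,
    iii) |s| >= 0.3  or  min(|CI_low|, |CI_high|) >= 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from zicpue.errors import UndefinedTestError

__all__ = [
    "CorrelationResult",
    "pearson_with_fisher_ci",
    "fisher_ci",
    "r_to_t",
    "t_to_r",
    "spearman_rho",
    "is_problematic",
    "screen_covariates",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson/Spearman summary for one covariate pair."""

    pair: tuple[str, str]
    n: int
    r: float
    t_stat: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    s: float = np.nan
    problematic: bool | None = None


def pearson_with_fisher_ci(
    x, y, conf: float = 0.95, pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Pearson r with Student-t significance and a Fisher-Z interval.

    t = r * sqrt(df / (1 - r^2)) with df = n - 2; the two-sided p-value
    comes from the t distribution, and the interval is
    tanh(atanh(r) +/- z / sqrt(n - 3)).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise UndefinedTestError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    df = n - 2
    t = r_to_t(r, df)
    p = 2.0 * stats.t.sf(abs(t), df)
    lo, hi = fisher_ci(r, n, conf)
    return CorrelationResult(
        pair=pair, n=n, r=r, t_stat=t, df=df, p=float(p), ci_low=lo, ci_high=hi
    )


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-Z confidence interval for a correlation coefficient.

    tanh(atanh(r) +/- z_{(1+conf)/2} / sqrt(n - 3)).
    """
    if n < 4:
        raise UndefinedTestError("need n >= 4 for a Fisher-Z interval")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    zr = np.arctanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    half = z / np.sqrt(n - 3)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))


def r_to_t(r: float, df: int) -> float:
    """Student-t statistic for a correlation: t = r sqrt(df / (1 - r^2))."""
    r = min(max(r, -1 + 1e-15), 1 - 1e-15)
    return float(r * np.sqrt(df / (1.0 - r**2)))


def t_to_r(t_stat: float, df: int) -> float:
    """Invert the correlation t-statistic: r = t / sqrt(t^2 + df)."""
    if df < 2:
        raise ValueError("df must be >= 2")
    return float(t_stat / np.sqrt(t_stat**2 + df))


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise UndefinedTestError(f"need at least 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def is_problematic(res: CorrelationResult, threshold: float = 0.3) -> bool:
    """Apply the three-criterion rule (sign-agnostic) to a complete result."""
    lo, hi = abs(res.ci_low), abs(res.ci_high)
    outer, inner = max(lo, hi), min(lo, hi)
    return bool(
        res.p < 0.05
        and outer >= threshold
        and (abs(res.s) >= threshold or inner >= threshold)
    )


def screen_covariates(
    table: pd.DataFrame, covariates: list[str], threshold: float = 0.3
) -> tuple[list[CorrelationResult], list[tuple[str, str]]]:
    """Screen every unordered covariate pair on pairwise-complete rows.

    Returns the per-pair results (lexicographic order) and the exclusion
    list of flagged pairs.  Pairs with too few complete observations or a
    constant member are skipped.
    """
    results = []
    exclusions = []
    for a, b in combinations(sorted(covariates), 2):
        x = table[a].to_numpy(float)
        y = table[b].to_numpy(float)
        try:
            res = pearson_with_fisher_ci(x, y, pair=(a, b))
            s = spearman_rho(x, y)
        except UndefinedTestError:
            continue
        res = replace(res, s=s)
        res = replace(res, problematic=is_problematic(res, threshold))
        results.append(res)
        if res.problematic:
            exclusions.append((a, b))
    return results, exclusions


def screen_report(results: list[CorrelationResult]) -> pd.DataFrame:
    """Flatten screening results into a report table."""
    return pd.DataFrame(
        [
            {
                "covariate_1": r.pair[0],
                "covariate_2": r.pair[1],
                "n": r.n,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_value": r.p,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "r": r.r,
                "s": r.s,
                "problematic": bool(r.problematic),
            }
            for r in results
        ]
    )
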