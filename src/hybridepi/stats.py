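"""Shared statistical primitives.

One Fisher engine serves both the differential-histone-modification and the
differential-expression calls; both compare replicate-pooled counts against
library remainders on a 2x2 table. The two-sided p-value is the sum of all
table probabilities no larger than the observed one (scipy's convention).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: pseudocount added to each proportion numerator in fold changes
LOG2FC_PSEUDOCOUNT = 0.5


def fisher_count_test(count_a: int, lib_a: int, count_b: int, lib_b: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on pooled counts vs library remainders.

    Returns ``(log2fc, pvalue)`` where the fold change is the ratio of
    pseudocounted proportions, first member over second:
    ``log2(((a+0.5)/lib_a) / ((b+0.5)/lib_b))``.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("count exceeds its library size")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    _, pvalue = sps.fisher_exact(table, alternative="two-sided")
    log2fc = math.log2(((count_a + LOG2FC_PSEUDOCOUNT) / lib_a) / ((count_b + LOG2FC_PSEUDOCOUNT) / lib_b))
    return log2fc, float(pvalue)


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial test p-value."""
    if n == 0:
        raise ValueError("n must be positive")
    return float(sps.binomtest(k, n, p, alternative="two-sided").pvalue)


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """One-sided upper binomial tail P(X >= k | n, p)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(sps.binom.sf(k - 1, n, p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def chi_squared_2x2(table) -> tuple[float, float]:
    """Chi-squared test of independence (1 df, no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined with an empty margin")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(numerator: float, denominator: float, decimals: int) -> float:
    """Percentage rendered at fixed precision, half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)
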