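"""Independent brute-force oracles used to verify the statistical engines.

Everything here is computed with exact rational arithmetic and naive
enumeration, deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def binomial_two_sided_half(k: int, n: int) -> float:
    """Exact two-sided binomial p at p=1/2: sum of P(X=j) with P(j) <= P(k)."""
    denom = Fraction(1, 2**n)
    probs = [comb(n, j) * denom for j in range(n + 1)]
    p_obs = probs[k]
    return float(sum(p for p in probs if p <= p_obs))


def binomial_upper_tail(k: int, n: int, p: Fraction) -> float:
    """P(X >= k) by direct summation."""
    p = Fraction(p)
    return float(sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)))


def bh_step_up(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * n / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def chi_squared_statistic(table: list[list[float]]) -> float:
    """Sum of (observed - expected)^2 / expected over a 2x2 table."""
    total = sum(sum(row) for row in table)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = sum(table[i]) * (table[0][j] + table[1][j]) / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat
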