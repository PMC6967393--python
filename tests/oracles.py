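"""Brute-force oracles, independent of the implementations they check.

Everything here works from first principles: exact integer binomial
coefficients, direct pmf summation, hand-rolled BH.  Slow on purpose —
only used at small n.
"""

from __future__ import annotations

import math
from fractions import Fraction


def binom_pmf(k: int, n: int, p: float) -> float:
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    log_pmf = (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    return math.exp(log_pmf)


def binom_two_sided(k_obs: int, n: int, p: float) -> float:
    """Two-sided minimum-likelihood binomial p-value: sum of pmf over all
    outcomes no more likely than the observed one."""
    d = binom_pmf(k_obs, n, p)
    total = 0.0
    for k in range(n + 1):
        if binom_pmf(k, n, p) <= d * (1 + 1e-10):
            total += binom_pmf(k, n, p)
    return min(total, 1.0)


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X = k) for k successes drawn in n trials from N items, K marked."""
    if k < 0 or k > min(K, n) or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for over-representation of the top-left
    cell in the 2x2 table [[a, b], [c, d]]: P(X >= a)."""
    N = a + b + c + d
    K = a + b  # row-1 total
    n = a + c  # column-1 total
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += hypergeom_pmf_exact(k, N, K, n)
    return float(total)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, by the textbook formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q
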