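"""Independent brute-force oracles used to freeze expected values.

Each oracle is a straight transcription of the defining formula, computed
with exact rational arithmetic (or plain floats where exactness is not at
issue), deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def ac_conditional_pmf(k: int, x: int, ratio: Fraction) -> Fraction:
    """P(k | x) for the count-difference null, ratio = N2/N1 (exact)."""
    return ratio**k * Fraction(math.comb(x + k, k)) / (1 + ratio) ** (x + k + 1)


def ac_pvalue_oracle(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact two-sided p: doubled smaller away-from-null conditional tail."""
    r = Fraction(n2, n1)
    upper = 1 - sum(ac_conditional_pmf(k, x, r) for k in range(y))       # P(Y>=y|x)
    lower = 1 - sum(ac_conditional_pmf(k, y, 1 / r) for k in range(x))   # P(X>=x|y)
    return min(Fraction(1), 2 * min(upper, lower))


def hypergeom_upper_tail_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact P(X >= a) by enumerating every table with the same margins."""
    population = a + b + c + d
    successes = a + c
    draws = a + b
    denom = Fraction(math.comb(population, draws))
    total = Fraction(0)
    for k in range(max(0, draws - (population - successes)), min(draws, successes) + 1):
        if k >= a:
            total += Fraction(
                math.comb(successes, k) * math.comb(population - successes, draws - k)
            ) / denom
    return total


def poisson_deviance_oracle(x, c, floor=1e-9) -> float:
    """Straight transcription of the deviance distance definition."""
    total = sum(x)
    d = 0.0
    for xj, cj in zip(x, c):
        lam = total * max(cj, floor)
        d += lam - xj
        if xj > 0:
            d += xj * math.log(xj / lam)
    return d
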