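"""Independent brute-force oracles used only by the test suite."""

import math
from fractions import Fraction


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of the hypergeometric
    support with exact integer weight comparisons (no floating point until
    the final division)."""
    n1, n2 = a + c, b + d
    total_carriers = a + b
    lo = max(0, total_carriers - n2)
    hi = min(n1, total_carriers)
    w_obs = math.comb(n1, a) * math.comb(n2, b)
    numerator = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(n1, k) * math.comb(n2, total_carriers - k)) <= w_obs
    )
    denominator = math.comb(n1 + n2, total_carriers)
    return float(Fraction(numerator, denominator))
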