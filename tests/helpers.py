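"""Independent oracles used across the test suite."""

from fractions import Fraction
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force one-sided Fisher p by exact enumeration.

    Sums hypergeometric point masses C(K,k)C(N-K,n-k)/C(N,n) over every
    integer table sharing the margins with focal-in-interval count k >= a,
    using exact rational arithmetic. Independent of any scipy code path.
    """
    K, n, N = a + b, a + c, a + b + c + d
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return float(total)
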