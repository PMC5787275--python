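"""Independent exact-arithmetic oracles used to verify the fast implementations.

Everything here works in rational arithmetic (math.comb + fractions.Fraction)
by direct enumeration of the hypergeometric sample space, deliberately sharing
no code with the package.
"""

from fractions import Fraction
from math import comb


def hypergeom_pmf_exact(x: int, n: int, row1: int, col1: int) -> Fraction:
    """P(top-left cell = x) for a 2x2 table with margins (row1, n-row1, col1)."""
    return Fraction(comb(row1, x) * comb(n - row1, col1 - x), comb(n, col1))


def fisher_p_exact(table, alternative: str = "two-sided") -> Fraction:
    """Fisher exact p by full enumeration over the conditional sample space."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {x: hypergeom_pmf_exact(x, n, row1, col1) for x in range(lo, hi + 1)}
    if alternative == "two-sided":
        return sum(p for p in pmf.values() if p <= pmf[a])
    if alternative == "greater":
        return sum(p for x, p in pmf.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in pmf.items() if x <= a)
    raise ValueError(alternative)


def all_tables_with_margins_up_to(max_margin: int):
    """Yield every 2x2 count table whose four margins are all <= max_margin."""
    for a in range(max_margin + 1):
        for b in range(max_margin + 1 - a):
            for c in range(max_margin + 1 - a):
                for d in range(max_margin + 1 - max(b, c)):
                    if a + b + c + d > 0:
                        yield ((a, b), (c, d))
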