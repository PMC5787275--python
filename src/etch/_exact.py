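"""Fisher's exact test for 2x2 tables, conditional on both margins.

The two-sided p-value sums the hypergeometric point probabilities of every
table (with the observed margins) whose probability does not exceed that of
the observed table, using a small relative guard against floating-point ties
(the convention of R's fisher.test). One-sided alternatives sum the
corresponding tail.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

_REL_GUARD = 1.0 + 1e-7


def odds_ratio_2x2(table) -> float:
    """Sample odds ratio ad/bc; inf when bc == 0 (and ad > 0), nan when both are 0."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if b * c == 0:
        return np.nan if a * d == 0 else np.inf
    return (a * d) / (b * c)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Exact (odds ratio, p) for a 2x2 contingency table.

    The table is ``[[a, b], [c, d]]``; conditioning on the margins, the
    top-left cell follows Hypergeom(N=a+b+c+d, K=a+b, n=a+c).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    a = t[0, 0]
    row1 = t[0].sum()
    col1 = t[:, 0].sum()
    n = t.sum()
    if n == 0:
        return np.nan, 1.0

    if alternative == "two-sided":
        support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
        pmf = hypergeom.pmf(support, n, row1, col1)
        p_obs = pmf[np.searchsorted(support, a)]
        p = pmf[pmf <= p_obs * _REL_GUARD].sum()
    elif alternative == "greater":
        p = hypergeom.sf(a - 1, n, row1, col1)
    elif alternative == "less":
        p = hypergeom.cdf(a, n, row1, col1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return odds_ratio_2x2(t), float(min(p, 1.0))
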