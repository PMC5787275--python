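"""Cross-species comparison of regulated gene sets through one-to-one orthologues.

Gene sets from two species are projected onto a universe of strictly
one-to-one orthologue pairs; each pair of sets is compared with Fisher's
exact test on the 2x2 table [both, A-only, B-only, neither] over that
universe. The full comparison matrix (all set x set cells, including
direction crosses such as A-up vs B-down) reports -log10 of the raw p
alongside BH-corrected p-values across all cells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._exact import fisher_exact_2x2
from .de_filter import bh_adjust
from .expression_io import GeneSet, OrthologyMap, logger


def filter_one_to_one(omap: OrthologyMap) -> list[tuple[str, str]]:
    """Orthologue pairs labelled one2one whose genes each occur exactly once.

    The uniqueness re-check over the whole map is defensive: a pair labelled
    one2one is dropped if either gene also participates in any other record.
    """
    df = omap.data
    count_a = Counter(df["geneA"])
    count_b = Counter(df["geneB"])
    kept = [
        (a, b)
        for a, b, rel in df.itertuples(index=False, name=None)
        if rel == "one2one" and count_a[a] == 1 and count_b[b] == 1
    ]
    n_labelled = int((df["relation"] == "one2one").sum())
    if len(kept) < n_labelled:
        logger.info("dropped %d one2one-labelled pairs failing uniqueness", n_labelled - len(kept))
    return kept


@dataclass(frozen=True)
class OverlapResult:
    """One cell of the cross-species comparison matrix."""

    setA_label: str
    setB_label: str
    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    neg_log10_p: float
    p_bh: float | None = None  # filled by overlap_matrix

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.both, self.a_only], [self.b_only, self.neither]])

    @property
    def expected_both(self) -> float:
        n = self.both + self.a_only + self.b_only + self.neither
        return (self.both + self.a_only) * (self.both + self.b_only) / n if n else np.nan


def overlap_test(
    setA: GeneSet, setB: GeneSet, pairs: Sequence[tuple[str, str]]
) -> OverlapResult:
    """Fisher exact overlap of two species' gene sets over an orthologue-pair universe.

    A pair is "in A" iff its species-A gene belongs to `setA`, likewise for B.
    Set members without a one-to-one pair are excluded (count logged).
    """
    if not pairs:
        raise ValueError("orthologue-pair universe is empty")
    genes_a = {a for a, _ in pairs}
    genes_b = {b for _, b in pairs}
    lost_a = len(setA.genes - genes_a)
    lost_b = len(setB.genes - genes_b)
    if lost_a or lost_b:
        logger.info(
            "%s vs %s: %d A genes and %d B genes lack a one-to-one pair",
            setA.label, setB.label, lost_a, lost_b,
        )
    in_a = np.fromiter((a in setA.genes for a, _ in pairs), bool, len(pairs))
    in_b = np.fromiter((b in setB.genes for _, b in pairs), bool, len(pairs))
    both = int((in_a & in_b).sum())
    a_only = int((in_a & ~in_b).sum())
    b_only = int((~in_a & in_b).sum())
    neither = len(pairs) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    oddsr, p_two = fisher_exact_2x2(table, alternative="two-sided")
    _, p_greater = fisher_exact_2x2(table, alternative="greater")
    return OverlapResult(
        setA_label=setA.label,
        setB_label=setB.label,
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        odds_ratio=oddsr,
        p_two_sided=p_two,
        p_greater=p_greater,
        neg_log10_p=float(-np.log10(p_two)) if p_two > 0 else np.inf,
    )


@dataclass
class OverlapMatrix:
    """All pairwise set comparisons, ordered by (A label, B label)."""

    results: list[OverlapResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "setA": r.setA_label,
                "setB": r.setB_label,
                "both": r.both,
                "a_only": r.a_only,
                "b_only": r.b_only,
                "neither": r.neither,
                "odds_ratio": r.odds_ratio,
                "p_two_sided": r.p_two_sided,
                "p_greater": r.p_greater,
                "neg_log10_p": r.neg_log10_p,
                "p_bh": r.p_bh,
            }
            for r in self.results
        )


def overlap_matrix(
    setsA: Sequence[GeneSet],
    setsB: Sequence[GeneSet],
    pairs: Sequence[tuple[str, str]],
) -> OverlapMatrix:
    """Compare every species-A set against every species-B set.

    All direction combinations are computed; BH correction runs across all
    cells of the matrix. -log10(p) is reported from the raw two-sided p, with
    the corrected p alongside.
    """
    if not setsA or not setsB:
        raise ValueError("need at least one gene set per species")
    results = [
        overlap_test(sa, sb, pairs)
        for sa in sorted(setsA, key=lambda s: s.label)
        for sb in sorted(setsB, key=lambda s: s.label)
    ]
    corrected = bh_adjust([r.p_two_sided for r in results])
    return OverlapMatrix([replace(r, p_bh=float(q)) for r, q in zip(results, corrected)])
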