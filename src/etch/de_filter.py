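"""Turn DE tables into direction-labelled significant gene sets.

Thresholds follow the study design: Benjamini-Hochberg adjusted p < 0.05
combined with a linear fold change above 1.25 (up) or below 1/1.25 (down),
both strict; transcripts with FPKM strictly above 2 count as actively
expressed. "Fold change greater than 1.25 or -1.25" is read as a linear
fold-change threshold, i.e. |log2fc| > log2(1.25), with the negative bound
meaning reciprocal down-regulation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .expression_io import DETable, GeneSet, logger


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1. Adjusted values are >= raw values and monotone non-decreasing
    in sorted order. Empty input yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de_sets(
    table: DETable,
    alpha: float = 0.05,
    fold_change: float = 1.25,
    label: str = "experiment",
) -> tuple[GeneSet, GeneSet]:
    """Significant up- and down-regulated gene sets at the study thresholds.

    A gene is up-regulated when ``padj < alpha`` and ``2**log2fc >
    fold_change``; down-regulated when ``padj < alpha`` and ``2**log2fc <
    1/fold_change``. ``padj`` is computed here by BH if the table lacks it.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if fold_change <= 1.0:
        raise ValueError("fold_change must be > 1")
    df = table.data
    padj = df["padj"].to_numpy(dtype=float) if "padj" in df.columns else bh_adjust(df["pvalue"])
    linear_fc = np.exp2(df["log2fc"].to_numpy(dtype=float))
    significant = padj < alpha
    up = significant & (linear_fc > fold_change)
    down = significant & (linear_fc < 1.0 / fold_change)
    genes = df["gene"].to_numpy()
    return (
        GeneSet(f"{label}_up", frozenset(genes[up]), direction="up"),
        GeneSet(f"{label}_down", frozenset(genes[down]), direction="down"),
    )


def flag_expressed(values: Sequence[float], threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of actively expressed transcripts (FPKM strictly > threshold)."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be non-negative")
    return v > threshold
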