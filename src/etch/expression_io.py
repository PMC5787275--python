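"""Readers, writers and validated containers for every file format the pipeline touches.

All tabular formats are TSV with dot decimals and UTF-8 encoding; gene
identifiers are opaque, case-sensitive strings. Readers validate eagerly and
raise :class:`FormatError` naming the offending record — nothing is silently
coerced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("etch")

#: The seven preimplantation stages, oocyte through blastocyst, in
#: developmental order. This is the default stage axis of every expression
#: matrix; a different (>= 2 stage) axis may be supplied explicitly.
STAGES: tuple[str, ...] = ("oocyte", "zygote", "2C", "4C", "8C", "morula", "blastocyst")

#: Closed vocabulary of orthology relation labels.
RELATIONS: frozenset[str] = frozenset({"one2one", "one2many", "many2one", "many2many"})


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class StageExpressionMatrix:
    """A genes x stages matrix of non-negative expression values (FPKM semantics).

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per stage, in
        developmental order. Values must be finite and non-negative.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.size < 2:
            raise FormatError("expression matrix needs at least 2 stages")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        values = data.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite expression value for gene {data.index[g]!r}, stage {data.columns[s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative expression value for gene {data.index[g]!r}, stage {data.columns[s]!r}"
            )
        self.data = data.astype(float)
        self.data.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def stages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, genes: Sequence[str]) -> "StageExpressionMatrix":
        """Row-subset preserving the order given in `genes`."""
        return StageExpressionMatrix(self.data.loc[list(genes)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StageExpressionMatrix) and self.data.equals(other.data)


DE_COLUMNS = ("gene", "log2fc", "pvalue", "mean_fpkm")


class DETable:
    """Per-gene differential-expression statistics from an ectopic-expression assay.

    Columns: ``gene``, ``log2fc`` (signed log2 fold change), ``pvalue`` (raw),
    optionally ``padj`` (BH-adjusted; filled by :mod:`etch.de_filter` when
    absent) and ``mean_fpkm``.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in DE_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"DE table missing columns: {missing}")
        if data["gene"].duplicated().any():
            dup = data.loc[data["gene"].duplicated(), "gene"].iloc[0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        data = data.copy()
        numeric = ["log2fc", "pvalue", "mean_fpkm"] + (["padj"] if "padj" in data.columns else [])
        data[numeric] = data[numeric].astype(float)
        for col in ("pvalue",) + (("padj",) if "padj" in data.columns else ()):
            p = data[col].to_numpy(dtype=float)
            bad = ~((p >= 0) & (p <= 1))
            if bad.any():
                gene = data.loc[np.flatnonzero(bad)[0], "gene"]
                raise FormatError(f"{col} outside [0, 1] for gene {gene!r}")
        self.data = data.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(self.data["gene"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class GeneSet:
    """A direction-labelled set of gene identifiers."""

    label: str
    genes: frozenset[str]
    direction: str | None = None  # "up" | "down" | None

    def __post_init__(self):
        if not self.label:
            raise ValueError("gene set label must be non-empty")
        if self.direction not in (None, "up", "down"):
            raise ValueError(f"direction must be 'up', 'down' or None, got {self.direction!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


class OrthologyMap:
    """Cross-species gene pairing with a relation label per pair."""

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ("geneA", "geneB", "relation") if c not in data.columns]
        if missing:
            raise FormatError(f"orthology map missing columns: {missing}")
        bad = ~data["relation"].isin(RELATIONS)
        if bad.any():
            tok = data.loc[bad, "relation"].iloc[0]
            raise FormatError(f"unknown relation token {tok!r}")
        if data.duplicated(subset=["geneA", "geneB", "relation"]).any():
            row = data[data.duplicated(subset=["geneA", "geneB", "relation"])].iloc[0]
            raise FormatError(f"duplicate orthology pair: {row['geneA']!r}/{row['geneB']!r}")
        self.data = data.reset_index(drop=True)

    @property
    def pairs(self) -> list[tuple[str, str, str]]:
        return list(self.data.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, stages: Sequence[str] = STAGES) -> StageExpressionMatrix:
    """Read a stage expression matrix TSV (header: gene<TAB>stage1...)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    expected = list(stages)
    if list(df.columns[1:]) != expected:
        raise FormatError(f"{path}: stage header {list(df.columns[1:])} != expected {expected}")
    try:
        matrix = StageExpressionMatrix(df.set_index("gene"))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    logger.debug("read %d genes x %d stages from %s", *matrix.shape, path)
    return matrix


def write_expression_matrix(matrix: StageExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(Path(path), sep="\t", index=True, float_format="%.10g")


def read_de_table(path: str | Path) -> DETable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    try:
        table = DETable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    logger.debug("read DE table with %d genes from %s", len(table), path)
    return table


def write_de_table(table: DETable, path: str | Path) -> None:
    table.data.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_orthology_map(path: str | Path) -> OrthologyMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        omap = OrthologyMap(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    logger.debug("read %d orthology pairs from %s", len(omap), path)
    return omap


def write_orthology_map(omap: OrthologyMap, path: str | Path) -> None:
    omap.data.to_csv(Path(path), sep="\t", index=False)


def read_gene_set(path: str | Path, label: str | None = None, direction: str | None = None) -> GeneSet:
    """Read a gene-set file: one identifier per line, '#' starts a comment."""
    path = Path(path)
    genes: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            genes.append(token)
    if not genes:
        logger.warning("gene-set file %s is empty", path)
    return GeneSet(label=label or path.stem, genes=frozenset(genes), direction=direction)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_set.genes)), encoding="utf-8")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file with a flat ``parameters:`` block."""
    import yaml

    path = Path(path)
    text = path.read_text(encoding="utf-8")
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
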