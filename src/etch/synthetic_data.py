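"""Synthetic preimplantation expression data with known planted structure.

The generators emulate the shape of the study system — a genes x 7-stage
(oocyte to blastocyst) FPKM matrix, per-experiment differential-expression
tables from ectopic-expression assays, and a two-species orthology map — while
planting ground truth (archetype membership, DE targets, shared orthologue
targets) so every downstream stage can be tested against a known answer.

Expression is modelled as ``scale_g * shape_a[s] * exp(eps)`` with gene-level
log-normal scales and multiplicative log-normal noise: trajectories keep their
archetype's shape, values stay non-negative, and dispersion grows with the
mean, as FPKM data does.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    DETable,
    OrthologyMap,
    StageExpressionMatrix,
    STAGES,
    logger,
    write_de_table,
    write_expression_matrix,
    write_orthology_map,
)

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ArchetypeSpec:
    """A temporal trajectory archetype.

    ``shape`` gives relative expression at each of the 7 stages in
    developmental order; genes of this archetype follow it up to a gene-level
    scale (log-normal with location ``base_scale_log_mean`` and spread
    ``base_scale_log_sd``, natural-log scale) and multiplicative noise.
    """

    name: str
    shape: tuple[float, ...]
    n_genes: int = 100
    base_scale_log_mean: float = 3.0
    base_scale_log_sd: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(float(x) for x in self.shape))
        if len(self.shape) != len(STAGES):
            raise ValueError(f"archetype {self.name!r}: shape must have {len(STAGES)} entries")
        if max(self.shape) <= 0:
            raise ValueError(f"archetype {self.name!r}: max(shape) must be > 0")
        if min(self.shape) < 0:
            raise ValueError(f"archetype {self.name!r}: shape entries must be non-negative")
        if self.n_genes < 1:
            raise ValueError(f"archetype {self.name!r}: n_genes must be >= 1")


#: Six fixed trajectory archetypes covering the classes of profile the
#: preimplantation literature describes: maternal transcript decay, a
#: two-cell ZGA pulse, a bimodal two-cell + blastocyst trajectory, an
#: eight-cell pulse, a late blastocyst rise, and a flat housekeeping-like
#: baseline. The numeric shapes are package constants, not measured values.
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("maternal_decay", (10.0, 6.0, 3.0, 1.5, 0.8, 0.4, 0.2)),
    ArchetypeSpec("two_cell_peak", (0.5, 1.0, 10.0, 2.0, 1.0, 0.5, 0.5)),
    ArchetypeSpec("two_cell_blastocyst", (0.5, 1.0, 8.0, 2.0, 1.0, 2.0, 12.0)),
    ArchetypeSpec("eight_cell_pulse", (0.5, 0.5, 1.0, 2.0, 10.0, 2.0, 1.0)),
    ArchetypeSpec("blastocyst_rise", (0.3, 0.3, 0.5, 1.0, 2.0, 5.0, 10.0)),
    ArchetypeSpec("flat", (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)),
)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic dataset."""

    gene_to_archetype: dict[str, str]
    planted_up: dict[str, set[str]] = field(default_factory=dict)
    planted_down: dict[str, set[str]] = field(default_factory=dict)
    planted_shared_pairs: set[tuple[str, str]] = field(default_factory=set)
    seed: int = 0

    def genes_of(self, archetype: str) -> list[str]:
        return [g for g, a in self.gene_to_archetype.items() if a == archetype]

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": TRUTH_SCHEMA_VERSION,
                "seed": self.seed,
                "gene_to_archetype": self.gene_to_archetype,
                "planted_up": {k: sorted(v) for k, v in self.planted_up.items()},
                "planted_down": {k: sorted(v) for k, v in self.planted_down.items()},
                "planted_shared_pairs": sorted(map(list, self.planted_shared_pairs)),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        if obj.get("schema_version") != TRUTH_SCHEMA_VERSION:
            raise ValueError(f"unsupported truth schema version {obj.get('schema_version')!r}")
        return cls(
            gene_to_archetype=obj["gene_to_archetype"],
            planted_up={k: set(v) for k, v in obj["planted_up"].items()},
            planted_down={k: set(v) for k, v in obj["planted_down"].items()},
            planted_shared_pairs={tuple(p) for p in obj["planted_shared_pairs"]},
            seed=obj["seed"],
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_stage_matrix(
    archetypes: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES,
    noise_log_sd: float = 0.25,
    seed: int = 0,
) -> tuple[StageExpressionMatrix, SyntheticTruth]:
    """Generate a stage expression matrix from trajectory archetypes.

    Each gene g of archetype a gets ``value[g, s] = scale_g * shape_a[s] *
    exp(eps[g, s])`` with ``eps ~ Normal(0, noise_log_sd^2)`` and
    ``scale_g ~ LogNormal(base_scale_log_mean, base_scale_log_sd)``.
    Deterministic given ``seed``.
    """
    if not archetypes:
        raise ValueError("at least one archetype is required")
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("archetype names must be unique")
    if noise_log_sd < 0:
        raise ValueError("noise_log_sd must be >= 0")

    rng = np.random.default_rng(seed)
    rows, genes, gene_to_archetype = [], [], {}
    for arch in archetypes:
        scales = rng.lognormal(arch.base_scale_log_mean, arch.base_scale_log_sd, arch.n_genes)
        eps = rng.normal(0.0, noise_log_sd, size=(arch.n_genes, len(STAGES)))
        block = scales[:, None] * np.asarray(arch.shape)[None, :] * np.exp(eps)
        rows.append(block)
        for i in range(arch.n_genes):
            gene = f"{arch.name}_{i:04d}"
            genes.append(gene)
            gene_to_archetype[gene] = arch.name
    data = pd.DataFrame(np.vstack(rows), index=genes, columns=list(STAGES))
    matrix = StageExpressionMatrix(data)
    truth = SyntheticTruth(gene_to_archetype=gene_to_archetype, seed=seed)
    return matrix, truth


def _normalize_fractions(value) -> tuple[float, float]:
    """Accept f (all up) or (f_up, f_down); validate range."""
    if isinstance(value, (int, float)):
        up, down = float(value), 0.0
    else:
        up, down = (float(v) for v in value)
    for f in (up, down):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"planted fraction {f} outside [0, 1]")
    if up + down > 1.0:
        raise ValueError("planted up + down fractions exceed 1 within an archetype")
    return up, down


def generate_de_table(
    matrix: StageExpressionMatrix,
    truth: SyntheticTruth,
    experiment: str,
    planted_fraction_by_archetype: Mapping[str, object] | None = None,
    effect_log2fc_mean: float = 2.0,
    seed: int = 0,
) -> DETable:
    """Generate a DE table with planted targets over-represented in chosen archetypes.

    Non-planted genes get ``p ~ Uniform(0, 1)`` and ``log2fc ~ Normal(0, 0.1)``;
    planted genes get ``log2fc ~ Normal(+-effect_log2fc_mean, 0.2)`` with the
    planted sign and ``p ~ Beta(0.01, 1)``. ``mean_fpkm`` is the gene's mean
    across stages in `matrix`. The planted up/down sets are recorded in
    `truth` under the `experiment` label.
    """
    planted_fraction_by_archetype = dict(planted_fraction_by_archetype or {})
    unknown = set(planted_fraction_by_archetype) - set(truth.gene_to_archetype.values())
    if unknown:
        raise ValueError(f"planted archetypes not present in matrix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    genes = matrix.genes
    up_set: set[str] = set()
    down_set: set[str] = set()
    for arch, frac in planted_fraction_by_archetype.items():
        f_up, f_down = _normalize_fractions(frac)
        members = truth.genes_of(arch)
        n_up = int(round(f_up * len(members)))
        n_down = int(round(f_down * len(members)))
        chosen = rng.choice(members, size=n_up + n_down, replace=False)
        up_set.update(chosen[:n_up])
        down_set.update(chosen[n_up:])

    missing = (up_set | down_set) - set(genes)
    if missing:
        raise ValueError(f"planted genes not present in matrix: {sorted(missing)[:5]}")

    n = len(genes)
    log2fc = rng.normal(0.0, 0.1, n)
    pvalue = rng.uniform(0.0, 1.0, n)
    idx = {g: i for i, g in enumerate(genes)}
    for gene_set, sign in ((up_set, 1.0), (down_set, -1.0)):
        ii = [idx[g] for g in sorted(gene_set)]
        log2fc[ii] = rng.normal(sign * effect_log2fc_mean, 0.2, len(ii))
        pvalue[ii] = rng.beta(0.01, 1.0, len(ii))

    table = DETable(
        pd.DataFrame(
            {
                "gene": genes,
                "log2fc": log2fc,
                "pvalue": pvalue,
                "mean_fpkm": matrix.values.mean(axis=1),
            }
        )
    )
    truth.planted_up[experiment] = up_set
    truth.planted_down[experiment] = down_set
    return table


def generate_orthology(
    n_pairs: int,
    frac_one_to_one: float = 0.8,
    shared_planted: Iterable[tuple[str, str]] = (),
    seed: int = 0,
    prefix_a: str = "mmu",
    prefix_b: str = "hsa",
) -> OrthologyMap:
    """Construct an orthology map with an exact count of one-to-one pairs.

    ``round(frac_one_to_one * n_pairs)`` pairs are labelled one2one (the
    construction is exact, not sampled); the remainder are one2many groups in
    which one species-A gene pairs with >= 2 species-B genes. All
    `shared_planted` pairs are emitted as one2one.
    """
    if not 0.0 <= frac_one_to_one <= 1.0:
        raise ValueError("frac_one_to_one must be in [0, 1]")
    shared = list(shared_planted)
    if len(shared) > n_pairs:
        raise ValueError(f"{len(shared)} shared planted pairs exceed n_pairs={n_pairs}")
    n_one = int(round(frac_one_to_one * n_pairs))
    if len(shared) > n_one:
        raise ValueError("shared planted pairs exceed the one-to-one allocation")
    n_many = n_pairs - n_one
    if n_many == 1:
        raise ValueError("a one-to-many remainder of a single pair is impossible; adjust frac_one_to_one")

    records: list[tuple[str, str, str]] = [(a, b, "one2one") for a, b in shared]
    for i in range(n_one - len(shared)):
        records.append((f"{prefix_a}_o2o_{i:05d}", f"{prefix_b}_o2o_{i:05d}", "one2one"))
    # one-to-many groups of 2 pairs; a final group of 3 absorbs an odd remainder
    group_sizes = [2] * (n_many // 2)
    if n_many % 2 and group_sizes:
        group_sizes[-1] += 1
    for gi, size in enumerate(group_sizes):
        gene_a = f"{prefix_a}_o2m_{gi:05d}"
        for j in range(size):
            records.append((gene_a, f"{prefix_b}_o2m_{gi:05d}_{j}", "one2many"))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    df = pd.DataFrame([records[i] for i in order], columns=["geneA", "geneB", "relation"])
    return OrthologyMap(df)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

DEFAULT_BUNDLE_CONFIG: dict = {
    "noise_log_sd": 0.25,
    "n_genes_per_archetype": 300,
    "experiments": {
        "factorA": {"eight_cell_pulse": [0.3, 0.0], "maternal_decay": [0.0, 0.3]},
        "factorB": {"two_cell_blastocyst": [0.3, 0.0]},
    },
    "effect_log2fc_mean": 2.0,
    "orthology": {"n_pairs": 1000, "frac_one_to_one": 0.8, "n_shared_planted": 50},
}


def write_fixture_bundle(outdir: str | Path, config: Mapping | None = None, seed: int = 0) -> dict:
    """Write a complete synthetic dataset (matrix, DE tables, orthology, truth).

    Returns a manifest mapping file names to sha256 checksums; the manifest is
    also written as ``manifest.json``. The output directory must already exist
    (no partial writes on a bad path).
    """
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    cfg = dict(DEFAULT_BUNDLE_CONFIG)
    cfg.update(config or {})

    archetypes = tuple(
        ArchetypeSpec(a.name, a.shape, n_genes=int(cfg["n_genes_per_archetype"]))
        for a in DEFAULT_ARCHETYPES
    )
    matrix, truth = generate_stage_matrix(archetypes, noise_log_sd=cfg["noise_log_sd"], seed=seed)
    files: dict[str, Path] = {"matrix.tsv": outdir / "matrix.tsv"}
    write_expression_matrix(matrix, files["matrix.tsv"])

    for i, (experiment, fractions) in enumerate(sorted(cfg["experiments"].items())):
        table = generate_de_table(
            matrix,
            truth,
            experiment,
            planted_fraction_by_archetype=fractions,
            effect_log2fc_mean=cfg["effect_log2fc_mean"],
            seed=seed + 1 + i,
        )
        name = f"de_{experiment}.tsv"
        files[name] = outdir / name
        write_de_table(table, files[name])

    ortho_cfg = cfg["orthology"]
    n_shared = int(ortho_cfg.get("n_shared_planted", 0))
    shared = [(f"mmu_shared_{i:04d}", f"hsa_shared_{i:04d}") for i in range(n_shared)]
    truth.planted_shared_pairs = set(shared)
    omap = generate_orthology(
        int(ortho_cfg["n_pairs"]),
        frac_one_to_one=ortho_cfg["frac_one_to_one"],
        shared_planted=shared,
        seed=seed + 100,
    )
    files["orthology.tsv"] = outdir / "orthology.tsv"
    write_orthology_map(omap, files["orthology.tsv"])

    files["truth.json"] = outdir / "truth.json"
    files["truth.json"].write_text(truth.to_json(), encoding="utf-8")

    manifest = {
        name: {
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            "bytes": path.stat().st_size,
        }
        for name, path in sorted(files.items())
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("wrote %d fixture files to %s", len(files), outdir)
    return manifest
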