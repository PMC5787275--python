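# etch

Temporal expression profiles, profile enrichment, and cross-species overlap
statistics for preimplantation transcriptomes.

## The problem

Mammalian preimplantation development (oocyte → zygote → 2-cell → 4-cell →
8-cell → morula → blastocyst) is driven by waves of transcription: maternal
transcripts decay, zygotic genome activation fires at the 2-cell stage in
mouse, and lineage programmes ramp up toward the blastocyst. A common analysis
pattern for this system is:

1. **Temporal profiles.** Cluster genes by the *shape* of their expression
   trajectory across the seven stages (variance filter, per-gene
   standardization, fuzzy c-means soft clustering into k profiles, then
   merging of highly correlated profiles into composite clusters).
2. **Profile enrichment.** Given a set of genes up- or down-regulated after
   ectopic expression of a transcription factor (a DESeq2-style DE table
   filtered at BH-adjusted p < 0.05 and linear fold change 1.25), ask which
   temporal profiles those genes concentrate in — via an iterative Pearson
   chi-square procedure with Fisher exact verification.
3. **Cross-species overlap.** Compare regulated gene sets between two species
   through strictly one-to-one orthologues, with pairwise Fisher exact tests
   over the orthologue-pair universe.

`etch` implements all three stages as a tested library plus a thin CLI, and
ships a synthetic-data generator that plants known structure (trajectory
archetypes, DE targets, shared orthologue targets) so every stage can be
validated against ground truth without any external download.

## The statistics at the core

**Fuzzy c-means** (fuzzifier m > 1, Euclidean distance d):

    u_gi = 1 / Σ_j (d_gi / d_gj)^(2/(m−1)),   c_i = Σ_g u_gi^m x_g / Σ_g u_gi^m

implemented as a scikit-learn estimator (`FuzzyCMeans`), alternating updates
until the centroids move less than `tol`.

**Profile enrichment.** With O_i DE genes observed in profile i and N_i
universe genes assigned to it, the proportionality gate is Pearson's
chi-square with E_i = n_de·N_i/N. While the gate rejects (p < 0.05), the
profile with the largest contribution (O_i−E_i)²/E_i is removed and the gate
re-run; each removed profile is verified by a two-sided Fisher exact test on
the original universe, BH-corrected across removed profiles.

**Overlap tests.** For gene sets A (species A) and B (species B) projected
onto one-to-one orthologue pairs, the 2×2 table [both, A-only, B-only,
neither] is tested exactly (hypergeometric), reporting the odds ratio,
two-sided and one-sided p, −log10 p, and BH-corrected p across a comparison
matrix.

## Worked example

```python
from etch import (build_profiles, call_de_sets, enrich,
                  read_de_table, read_expression_matrix)
from etch.synthetic_data import write_fixture_bundle
from pathlib import Path

out = Path("demo"); out.mkdir(exist_ok=True)
write_fixture_bundle(out, {"n_genes_per_archetype": 200}, seed=1)

matrix = read_expression_matrix(out / "matrix.tsv")
profiles = build_profiles(matrix, k=12, seed=1)
up, down = call_de_sets(read_de_table(out / "de_factorA.tsv"), label="factorA")
report = enrich(up, profiles)
hit = report.table.set_index("profile_id").loc[report.enriched_profiles()[0]]
print(len(up), report.enriched_profiles(), f"{hit.fisher_p_bh:.2e}")
```

prints

```
57 [7] 1.74e-46
```

meaning: 57 genes pass the DE filter in the up direction (the generator
planted 60 up-regulated targets in the eight-cell-pulse trajectory); the
chi-square gate rejects proportionality, the iterative procedure removes
profile 7 — the profile holding every one of those DE genes — first, and
Fisher verification on the original universe calls it enriched with
corrected p = 1.74e-46. The same pipeline is available from the shell as
`etch simulate | profiles | enrich | xspecies`.

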