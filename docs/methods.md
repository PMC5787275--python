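# Methods

## Scope and data model

The pipeline operates on three inputs: a genes × 7-stage expression matrix
with FPKM semantics (stages oocyte, zygote, 2C, 4C, 8C, morula, blastocyst,
in developmental order), per-experiment differential-expression tables
(gene, log2 fold change, raw p, mean FPKM), and a two-species orthology map
with relation labels (one2one, one2many, many2one, many2many). Expression
values are ingested, never computed: read alignment, FPKM estimation and
DE model fitting are upstream of this package and out of scope.

## Synthetic data generator

The generator emulates the structure of preimplantation RNA-seq compendia
so that every downstream stage can be tested against planted truth.

**Expression model.** Each gene g of archetype a has

    value[g, s] = scale_g · shape_a[s] · exp(ε_gs),
    scale_g ~ LogNormal(μ=3, σ=1),  ε_gs ~ Normal(0, noise_log_sd²)

Multiplicative log-normal noise keeps values non-negative and gives a
dispersion that grows with the mean, the qualitative behaviour of FPKM data.
The default `noise_log_sd = 0.25` produces stage-to-stage scatter that
leaves trajectory shape clearly recoverable while exercising the soft
clustering meaningfully; 0 disables noise for exact-recovery fixtures.

**Archetype library.** Six fixed 7-vectors encode the trajectory classes the
preimplantation literature describes: maternal decay (monotone decrease from
a high oocyte level), a two-cell ZGA pulse, a bimodal two-cell + blastocyst
trajectory with the larger second peak, an eight-cell pulse, a late
blastocyst rise, and a flat baseline. The numbers are package constants
chosen for shape, not measurements. The flat archetype is constant and is
therefore removed by any positive variance filter — a deliberate property
used to test the filter.

**DE tables.** Non-planted genes receive p ~ Uniform(0,1) and
log2FC ~ Normal(0, 0.1); planted targets receive log2FC ~ Normal(±effect,
0.2) with the planted sign and p ~ Beta(0.01, 1) (a spike near zero). The
default effect of 2 log2 units makes planted direction essentially always
recoverable, which is what a positive-control fixture should do. DE tables
are generated directly rather than via count simulation and refitting,
because DE model fitting is out of scope; consequently the generator does
not emulate mean–variance coupling of p-values or DESeq2's independent
filtering.

**Orthology.** The one-to-one fraction is constructed exactly (counted, not
sampled); the remainder is emitted as one-to-many groups in which one
species-A gene pairs with at least two species-B genes. A remainder of
exactly one pair cannot form such a group and raises an error rather than
mislabelling. Planted shared pairs are always one-to-one so they survive the
downstream filter.

All generators are deterministic given a seed. The fixture bundle writes a
versioned truth JSON (`schema_version`) plus a sha256 manifest, so fixtures
are byte-stable across runs.

**What passing tests do not show.** The generator draws independent genes;
real data have correlated co-expression modules, batch effects, and
heavier-tailed noise. Calibration and recovery results on synthetic data
therefore bound behaviour under the model's assumptions, not under every
real-data pathology.

## Temporal profiles

- **Variance filter:** sample variance (denominator n−1) across stages,
  strictly greater than the threshold (default 5, FPKM² units). Sample
  variance is the common default where an estimator is unstated; strictness
  follows the "greater than" convention used throughout.
- **Standardization:** per-gene z-score (mean 0, sample sd 1), so clustering
  sees trajectory shape rather than expression magnitude. Standardized rows
  are signed and are handled as plain DataFrames, not FPKM matrices.
- **Fuzzy c-means:** fuzzifier m = 1.25 by default — a conventional choice
  for standardized expression trajectories, soft enough to expose ambiguous
  genes while keeping clusters crisp; k = 150 initial profiles by default,
  both config-exposed (desk-scale tests use much smaller k). Centroids are
  initialized from sampled data rows with D²-weighting (k-means++ style):
  with duplicated trajectories in the data, plain uniform sampling can seed
  two coincident centroids that then collapse onto each other, which
  D²-weighting avoids while remaining deterministic given the seed.
  Convergence when the largest centroid coordinate change falls below 1e-6,
  capped at 1000 iterations. Rows that coincide with a centroid (distance
  ≤ 1e-12) get membership 1 split across the coincident centroids. Hard
  assignment is argmax membership with no minimum-membership floor, ties to
  the lowest profile id.
- **Merging:** Pearson correlation between centroids; pairs above
  r = 0.95 define a graph. A connected component whose correlations are all
  reciprocal (a clique) merges wholesale. Otherwise the component is split
  by average-linkage (UPGMA) clustering on distance 1−r, cut at 1−r_threshold;
  the linkage is implemented directly (components are small) so that
  equal-distance merges can be broken deterministically in favour of the
  pair containing the lowest profile id, with distances within 1e-9 treated
  as tied. Composite clusters get ids 201, 202, … in order of their smallest
  member id; the composite centroid is the assigned-gene-count-weighted mean
  of member centroids, re-standardized (equal weights if no genes are
  assigned). Memberships are summed across merged columns; assignments are
  remapped. Merging on centroid correlation (rather than mean member
  expression) is a documented choice; re-standardizing composites keeps all
  centroids on one scale.
- Empty profiles are retained in the ProfileSet but excluded from enrichment
  universes (a profile with no universe genes has undefined expected count).

## DE filtering

Benjamini–Hochberg step-up adjustment (via statsmodels) followed by strict
thresholds: adjusted p < 0.05 and linear fold change > 1.25 (up) or
< 1/1.25 (down), i.e. |log2FC| > log2 1.25 ≈ 0.3219. The fold-change bound
is interpreted on the linear scale with the negative bound meaning
reciprocal down-regulation. Transcripts with FPKM strictly above 2 count as
actively expressed. BH re-adjustment of already-adjusted values is not
idempotent in general and is not claimed.

## Profile enrichment

The null hypothesis is proportionality: E_i = n_de·N_i/N. One profile is
removed per iteration — the largest Pearson contribution (O−E)²/E, ties to
the lowest id — and the gate re-run, stopping when the gate p reaches
gate_alpha (0.05), only two profiles remain, the removal cap (k/2 by
default) is hit, or no DE genes remain in the reduced table. Removing one
profile at a time and re-testing keeps the rule deterministic and avoids
over-removal when one strong profile inflates the residuals of others.

Fisher verification of each removed profile is computed on the **original**
pre-removal universe, so each reported table is interpretable on its own;
two-sided p-values are BH-corrected across removed profiles (consistent with
the DE filter's correction). A removed profile is called enriched when
corrected p < gate_alpha and odds ratio > 1, depleted when the odds ratio is
< 1. The default universe is all genes carrying a profile assignment,
intersected with the DE experiment's testable genes when supplied; the
universe is always explicit and overridable. A warning (not pooling) is
emitted when any expected count is below 5, where the chi-square
approximation weakens.

The in-package Fisher exact test conditions on both margins; the two-sided p
sums hypergeometric point probabilities not exceeding the observed table's,
with a 1e-7 relative guard against floating-point ties (the convention of
R's fisher.test); one-sided p-values use the hypergeometric tail directly.
The odds ratio is the sample odds ratio ad/bc (∞ when bc = 0 and ad > 0,
undefined when both products vanish).

## Cross-species overlap

One-to-one filtering keeps pairs labelled one2one whose genes each occur
exactly once anywhere in the map (a defensive re-check against inconsistent
labels). Overlap tests project each species' gene set onto the pair
universe; set members without a surviving pair are excluded and counted in
the log. The comparison matrix computes all A×B cells including direction
crosses (A-up vs B-down and so on), orders output lexicographically by set
labels, reports −log10 of the raw two-sided p (the per-test quantity), and
BH-corrects across all cells of the matrix alongside.

## Validation design and problem sizes

- Exact-test equivalence is checked against an independent
  rational-arithmetic enumeration oracle on every 2×2 table with all four
  margins ≤ 12 (5550 tables) and on 200 random larger tables.
- Gate calibration uses 20 profiles with sizes drawn once in 200–800, 500 DE
  genes assigned multinomially in proportion to profile size, 2000
  replicates; the rejection rate is required to sit in the central 99.9%
  binomial band around 0.05. Multinomial (with-replacement) assignment is
  the sampling model under which Pearson's test is calibrated; without-
  replacement draws from a finite universe would make the gate slightly
  conservative by the finite-population correction.
- Planted-enrichment recovery plants 90 of 150 DE genes in a profile holding
  one tenth of a 1000-gene universe (6× its expected 15) and requires the
  profile to be removed first and called enriched at corrected p < 1e-6 in
  ≥ 95% of 200 seeds.
- Cross-species power plants an overlap of 30 between two 100-gene sets over
  1000 pairs (expected overlap 10) and requires one-sided p < 1e-6 in ≥ 95%
  of 200 seeds.
- Null calibration of the overlap test draws set membership independently
  per gene (inclusion 0.12 per species) over a 20 000-pair universe — the
  scale of a real genome-wide one-to-one orthologue set — and requires the
  one-sided p over 500 seeds to pass a Kolmogorov–Smirnov uniformity test at
  the 0.01 level. The genome-scale universe matters statistically, not just
  cosmetically: an exact test's p-value is discrete, and over small
  universes the gaps between attainable p-values (up to the maximal
  hypergeometric point mass, ~0.14 at 100/100/1000) make any correctly
  implemented exact test measurably super-uniform, which a KS test at n=500
  reliably flags. At genome scale the support is dense and the residual
  conservatism is far below KS resolution. Set sizes vary binomially across
  seeds, as the DE generator itself produces.

These sizes keep the full validation run around a minute on one CPU while
leaving each check statistically meaningful.

## Known limitations

- The fuzzy c-means objective is non-convex; different seeds can reach
  different local optima at large k. Desk-scale recovery tests use k equal
  to the number of planted archetypes.
- The iterative removal rule tests profiles one at a time; two profiles
  inflated in opposite directions are removed sequentially, and the reported
  directions refer to the residual sign at the iteration of removal.
- BH correction across removed profiles controls FDR only over the profiles
  actually removed, not over all k profiles.
- The chi-square gate relies on the large-sample approximation; with many
  near-empty profiles (expected counts < 5) the emitted warning should be
  taken seriously — the package does not pool small profiles.
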