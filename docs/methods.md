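# Methods

## Model and procedure

The input is an `n × R` label matrix: `n` cohort samples, `R` clustering
runs, integer cluster labels with explicit missing entries. Label alphabets
are arbitrary per run — only within-column equality carries information —
and labels are deliberately never canonicalized, so file round-trips are
bit-exact.

### Consensus weights with pairwise-available-case denominators

For a pair (i, j), `together(i, j)` counts runs where both samples are
observed *and* share a label, `observed(i, j)` counts runs where both are
observed, and `CW = together / observed`. Dividing by the total number of
runs instead would count shared missingness as similarity, which is
precisely the failure mode this package exists to remove; the
pairwise-available-case denominator is therefore fixed, not configurable.
Pairs never co-observed have no defined CW and are carried as explicit NA,
never imputed.

### The permutation null and NCW

Each column is permuted uniformly among its *observed* positions; missing
positions never move. This null keeps three things fixed — the per-run
label composition, the per-run coverage, and the entire missingness
pattern — and destroys only the sample-to-sample association. Because the
missingness is fixed, `observed(i, j)` is permutation-invariant, so
"permuted CW ≥ observed CW" reduces to an integer comparison of
co-assignment counts; only the numerators are recomputed per permutation.

The p-value is the one-sided add-one permutation estimator
`P = (exceed + 1) / (nperm + 1)`, with exceedance counted with the weak
inequality (≥) and *per pair*, against that pair's own permuted
distribution. `NCW = 1 − P`, hence `NCW ∈ [0, 1)` strictly: no finite
number of permutations can certify impossibility. Two consequences define
the method's behaviour:

- a pair co-observed only in constant-label runs always ties its null, so
  `exceed = nperm` and `NCW = 0` exactly — uninformative co-clustering
  carries no weight;
- two pairs with the same raw CW but different amounts of evidence (2 vs
  10 informative runs) separate, because the richer null has more ways to
  fail to reach the observed CW.

An alternative null would pool permuted CWs across pairs into one ECDF;
with unequal coverage the pairs are not exchangeable, so the per-pair null
is the defensible choice and the only one implemented.

Never-co-observed pairs have no defined null. The default policy is a hard
error pointing at coverage filtering; an explicit `zero` policy assigns
NCW 0 with a logged warning for exploratory use. The choice is surfaced
rather than silently guessed because a zero is a strong statement (maximal
dissimilarity) about a pair the data says nothing about.

### Permutation bookkeeping and stability

Permutations run in blocks of 1000 (configurable). One master seed spawns
one child `SeedSequence` per block, so blocks are independently
reproducible and the result is a deterministic function of
`(matrix, seed, nperm_blocks, block_size)`. Inside a block, permutations
are drawn in vectorized chunks: per column, uniform keys are argsorted to
produce uniform random placements of the observed labels, and
co-assignment counts for a whole chunk accumulate through one boolean
broadcast. This is an optimization only; it is checked against a
brute-force pair×run counting oracle and against exhaustive enumeration of
small arrangement spaces.

After every block the cumulative NCW estimate is snapshotted; block b ≥ 2
records the squared differences to the previous snapshot over defined
upper-triangle pairs and their sum. Since the estimate is a cumulative
average, the sums decay roughly as 1/b²; a final-block sum far below the
block-2 sum indicates convergence, and the boxes-plus-line stability plot
visualizes the trace.

### Consensus clustering of the NCW matrix

Monti-style resampling on the similarity `NCW` (distance `1 − NCW`): for
each k = 2..maxK, `reps` iterations subsample `⌈p_item · n⌉` samples
without replacement, cluster the induced submatrix, and accumulate
connectivity and co-sampling indicators; the consensus matrix is their
ratio (0, with a warning, for pairs never co-sampled). Inner algorithms:

- **hierarchical** (default): scipy agglomerative linkage (average /
  complete / ward) on the distance submatrix;
- **spectral**: the NCW submatrix is used directly as an affinity
  (normalized-Laplacian embedding + seeded k-means) — a similarity method
  should consume the similarity un-negated;
- **k-medoids**: a seeded PAM-style implementation (k-medoids++
  initialization, alternating assignment/medoid update), written in-package
  because no installed library provides one.

The final tree is an agglomerative clustering of `1 − consensus`, cut into
exactly k clusters (`scipy.cluster.hierarchy.cut_tree`, which guarantees k
non-empty clusters). scipy's linkage is deterministic for a given input
array, which is what the reproducibility guarantee (manifests, byte-stable
outputs) requires; no custom tie-break is layered on top.

Model selection uses the empirical CDF of upper-triangle consensus values
on a fixed 100-interval grid over [0, 1]; the area is a left Riemann sum,
so an all-ones consensus matrix has area exactly 0. `delta_area(2) =
area(2)`; for k > 2 it is the relative increase over k − 1. By default the
chosen k is the argmax of delta area over k ≥ 3 (ties to the smaller k);
`delta_area(2)` is an absolute area and not comparable to the relative
increases, so k = 2 is reachable only through the optional elbow-threshold
rule (largest k whose delta area exceeds the threshold). Defaults
`reps = 100`, `p_item = 0.8`, `maxK = 6` follow common consensus-clustering
practice; they are package defaults, not claims about any published
analysis.

Cluster consensus of cluster c is the mean consensus over distinct pairs
within c (0 for singletons, by convention); item consensus of sample i
toward c is the mean consensus between i and members of c other than i.

## Synthetic cohorts

The generator emulates the label-matrix structure that integrative
pipelines produce, not the omics data underneath: a latent partition drawn
from cluster proportions (redrawn, boundedly, until every cluster is
non-empty), per-run coverage drawn uniformly from a range with each sample
observed independently, and a `noise_rate` fraction of observed labels
flipped to a uniformly-chosen *different* cluster (per-run k stays at
k_true). Optional tiers tie an n-omics level to a coverage range, emulating
the fact that richer omics combinations cover fewer samples, and populate
the run-metadata sidecar used by the EQUAL/LARGER selection strategies.

Default study conditions: 60 samples, 3 equal clusters, 30 runs, coverage
0.4–1.0, 10% noise — a desk-scale analogue of a real cohort with hundreds
of omics-combination runs and existing-sample rates from ~35 to 100%. What
the generator does **not** model: correlated missingness across runs
sharing a platform, correlated errors across runs built from overlapping
omics, unequal per-run cluster numbers, and batch structure. Passing
recovery tests therefore show the pipeline's statistical machinery is
correct under independent missingness and noise; they do not certify
performance on cohorts with strongly dependent runs.

NMI uses the sqrt normalization `MI / sqrt(H(a)·H(b))` (max-normalization
available via `method="max"`). When either entropy is zero the ratio is
undefined; the stated convention (1 if the partitions are identical as
set-partitions, else 0) is implemented explicitly because library defaults
disagree on this corner.

## Numerical choices and degenerate inputs

- Coverage filtering is inclusive (`≥ min_rate`), the conservative reading
  of "threshold".
- Validation rejects columns with fewer than 2 observed entries (they carry
  no pairwise information) and non-positive labels; coverage is always
  recomputed, never trusted from metadata.
- TSV floats are written with `%.10g` and JSON with sorted keys, so equal
  results are byte-equal; manifests carry timestamps, numeric outputs do
  not.
- Chunk sizes in the permutation engine adapt to `n² · R` to bound memory
  (~tens of MB); they affect speed only, not results.

## Problem sizes and limitations

Tests and the acceptance script run the full pipeline at 60 samples ×
30 runs with 10 permutation blocks (seconds per run), plus 20-seed
stability/monotonicity sweeps at 8–12 samples; these sizes give tight
Monte-Carlo bounds (3σ binomial against exhaustive enumeration) while
staying desk-scale. The engine handles hundreds of samples and runs; cost
grows as `n² · R` per permutation. Known limitations: no analytic null
(permutation only), no PAC statistic or bootstrap significance for k, and
NCW = 0 under the `zero` policy conflates "no evidence" with "evidence of
dissimilarity" — prefer coverage filtering.
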