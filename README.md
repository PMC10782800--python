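# ncwcluster

Consensus clustering for cluster ensembles with **missing labels**.

## The problem

Integrative subtyping of clinical cohorts often produces many clustering
runs for the same samples — for example one run per multi-omics combination
fed through network fusion and spectral clustering. Because every omics
platform covers a different subset of subjects, the runs have *unequal
sample coverage*: a sample simply has no label in a run whose underlying
data it lacks. Classical consensus clustering (cluster ensembling) scores a
sample pair by its co-association

```
CW(i, j) = (# runs where i and j share a cluster) / (# runs where both are observed)
```

but this raw rate cannot tell a pair that co-clusters in many informative
runs from a pair that co-clusters in two runs that put everyone in one
cluster: both score 1. With heavy missingness, chance and uninformative
co-clustering masquerade as similarity.

`ncwcluster` implements a two-step remedy:

1. **Normalized consensus weights (NCW).** Each column of the label matrix
   is permuted many times *with missing positions held fixed*, preserving
   the per-run label composition and the exact missingness pattern. For
   each pair, the one-sided empirical p-value of its observed CW against
   its own permuted distribution is computed with the add-one estimator
   `P = (exceed + 1) / (nperm + 1)`, and `NCW = 1 − P`. Pairs whose
   co-clustering is fully explained by the null (e.g. constant-label runs)
   drop to NCW = 0; pairs backed by many informative runs keep NCW near 1.
   A per-block stability trace (sum of squared NCW changes per 1000
   permutations) shows when the estimate has converged.
2. **Resampling consensus clustering** of the NCW matrix (Monti-style):
   for each k = 2..maxK, samples are repeatedly subsampled and clustered
   (hierarchical, spectral or k-medoids) on the induced NCW submatrix; the
   consensus matrix, tree and class assignment, cluster-/item-consensus
   tables, and CDF/delta-area diagnostics select the final partition.

## Worked example

```python
from ncwcluster import (SyntheticSpec, generate_cohort, compute_ncw,
                        ConsensusRunConfig, consensus_cluster_ncw, nmi)

spec = SyntheticSpec(n_samples=60, k_true=3, n_runs=30,
                     coverage_range=(0.4, 1.0), noise_rate=0.1, seed=1)
cohort = generate_cohort(spec)            # per-run coverage 0.42-1.00
ncw = compute_ncw(cohort.matrix, nperm_blocks=10, seed=1)
res = consensus_cluster_ncw(ncw, ConsensusRunConfig(maxK=6, seed=1))
print(res.chosen_k)                                  # 3
print({k: round(v, 3) for k, v in res.delta_area.items()})
# {2: 0.439, 3: 0.541, 4: 0.022, 5: 0.029, 6: 0.025}
print(nmi(res.per_k[3].consensus_class, cohort.truth))  # 1.0
```

A cohort of 60 samples in 3 true groups is observed through 30 runs whose
coverage spans 42–100% and whose labels carry 10% noise. The delta-area
curve peaks sharply at k = 3 (0.541 against ≤ 0.03 for k ≥ 4), so the
pipeline selects 3 clusters, and the recovered partition matches the
ground truth exactly (NMI = 1.0). The permutation stability trace decays
from 0.0146 (block 2) to 0.0003 (block 10), indicating 10 blocks of 1000
permutations are ample at this problem size.

The same pipeline from the shell:

```bash
ncwcluster simulate --n-samples 60 --k-true 3 --n-runs 30 --seed 1 --out-dir sim/
ncwcluster cluster --input sim/matrix.tsv --nperm 10 --maxk 6 --seed 1 \
    --plots --out-dir out/
```

`out/` then holds `ncw.tsv`, `stability.tsv`, per-k consensus matrices and
class assignments, `itemConsensus.tsv`/`clusterConsensus.tsv`,
`summary.json` (chosen k, areas, delta areas, config echo) and a
`manifest.json` sufficient to reproduce the run bit-identically. Real
label matrices are plain TSV (rows = samples, columns = runs, `NA` =
missing); `--min-coverage` filters runs by their existing-sample rate and
`--strategy equal|larger --n-omics N --run-meta meta.tsv` selects runs by
the number of omics platforms behind them.

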