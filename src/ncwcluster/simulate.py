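"""Synthetic missing-label cohorts with known ground truth, and NMI scoring.

The generator emulates the statistical structure of a cohort in which many
clustering runs — one per multi-omics combination — are available for
overlapping but unequal subsets of samples: a latent true partition, per-run
sample coverage drawn from a range (real cohorts span roughly 35-100%), and
a fraction of observed labels corrupted to a different cluster.  Optional
tiers tie the number of omics platforms behind a run to its coverage, which
is the mechanism that makes richer omics combinations cover fewer samples.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.cluster import normalized_mutual_info_score

from .labels_io import MISSING, LabelMatrix, write_label_matrix, write_run_meta

_MAX_COLUMN_RETRIES = 100


@dataclasses.dataclass(frozen=True)
class TierSpec:
    """A group of runs sharing an n-omics level and a coverage range."""

    n_omics: int
    n_runs: int
    coverage_range: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``noise_rate`` is the fraction of observed labels reassigned, uniformly,
    to a different cluster; ``coverage_range`` bounds the per-run Bernoulli
    observation probability.  When ``tiers`` is given it overrides
    ``n_runs``/``coverage_range`` and attaches per-run n_omics metadata.
    """

    n_samples: int = 60
    k_true: int = 3
    n_runs: int = 30
    coverage_range: tuple[float, float] = (0.4, 1.0)
    noise_rate: float = 0.1
    cluster_proportions: tuple[float, ...] | None = None
    tiers: tuple[TierSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must lie in [0, 1)")
        lo, hi = self.coverage_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("coverage_range must satisfy 0 < lo <= hi <= 1")
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            if p.size != self.k_true or (p <= 0).any():
                raise ValueError("cluster_proportions must be k_true positives")
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("cluster_proportions must sum to 1")

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.k_true, 1.0 / self.k_true)
        return np.asarray(self.cluster_proportions, dtype=float)


@dataclasses.dataclass
class SyntheticCohort:
    matrix: LabelMatrix
    truth: np.ndarray  # per-sample true cluster in 1..k_true
    spec: SyntheticSpec


def _draw_column(
    truth: np.ndarray, coverage: float, noise_rate: float,
    k_true: int, rng: np.random.Generator,
) -> np.ndarray:
    """One run: Bernoulli(coverage) observation, then label noise."""
    n = truth.size
    for _ in range(_MAX_COLUMN_RETRIES):
        obs = rng.random(n) < coverage
        if obs.sum() >= 2:
            break
    else:
        raise RuntimeError(
            f"could not draw a column with >= 2 observed samples at "
            f"coverage {coverage:g}"
        )
    col = np.full(n, MISSING, dtype=np.int64)
    col[obs] = truth[obs]
    idx = np.nonzero(obs)[0]
    n_flip = int(round(noise_rate * idx.size))
    if n_flip:
        flip = rng.choice(idx, size=n_flip, replace=False)
        # uniformly different cluster: shift by 1..k-1 mod k
        shift = rng.integers(1, k_true, size=n_flip)
        col[flip] = (col[flip] - 1 + shift) % k_true + 1
    return col


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a cohort: truth by proportions, then one column per run."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    p = spec.proportions()
    for _ in range(_MAX_COLUMN_RETRIES):
        truth = rng.choice(np.arange(1, spec.k_true + 1), size=spec.n_samples,
                           p=p)
        if np.unique(truth).size == spec.k_true:
            break
    else:
        raise RuntimeError("could not draw a truth with all clusters non-empty")

    if spec.tiers is not None:
        plan = [
            (t.n_omics, t.coverage_range)
            for t in spec.tiers
            for _ in range(t.n_runs)
        ]
    else:
        plan = [(None, spec.coverage_range)] * spec.n_runs

    cols, meta_rows, run_ids = [], [], []
    for j, (n_omics, (lo, hi)) in enumerate(plan):
        c = rng.uniform(lo, hi)
        cols.append(_draw_column(truth, c, spec.noise_rate, spec.k_true, rng))
        run_ids.append(f"run{j + 1}")
        if n_omics is not None:
            meta_rows.append({"run_id": run_ids[-1], "n_omics": n_omics})
    labels = np.column_stack(cols)
    meta = (
        pd.DataFrame(meta_rows).set_index("run_id") if meta_rows else None
    )
    sample_ids = [f"S{i + 1}" for i in range(spec.n_samples)]
    matrix = LabelMatrix(sample_ids, run_ids, labels, meta)
    return SyntheticCohort(matrix=matrix, truth=truth, spec=spec)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write matrix.tsv, truth.tsv, spec.json (and run_meta.tsv with tiers)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_label_matrix(cohort.matrix, out / "matrix.tsv")
    pd.DataFrame(
        {"sample_id": cohort.matrix.sample_ids,
         "true_cluster": cohort.truth}
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    if cohort.matrix.run_meta is not None:
        write_run_meta(cohort.matrix.run_meta, out / "run_meta.tsv")
    spec_dict = dataclasses.asdict(cohort.spec)
    (out / "spec.json").write_text(
        json.dumps(spec_dict, indent=2, sort_keys=True, default=list) + "\n"
    )


# ---------------------------------------------------------------------------
# Partition scoring


def _canonical(partition: np.ndarray) -> np.ndarray:
    """Relabel by first occurrence so set-partition equality is array equality."""
    _, canon = np.unique(partition, return_inverse=True)
    first_seen: dict[int, int] = {}
    out = np.empty(partition.size, dtype=np.int64)
    for i, v in enumerate(canon.tolist()):
        out[i] = first_seen.setdefault(v, len(first_seen))
    return out


def nmi(a: Sequence[int], b: Sequence[int], method: str = "sqrt") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Normalization divides MI by ``sqrt(H(a) * H(b))`` (``method="sqrt"``,
    the default) or by ``max(H(a), H(b))`` (``method="max"``).  When either
    partition has zero entropy the ratio is undefined; by convention the
    score is 1 if the two are identical as set-partitions and 0 otherwise.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and of equal length")
    if method not in ("sqrt", "max"):
        raise ValueError("method must be 'sqrt' or 'max'")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        return 1.0 if np.array_equal(_canonical(a), _canonical(b)) else 0.0
    avg = "geometric" if method == "sqrt" else "max"
    return float(normalized_mutual_info_score(a, b, average_method=avg))
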