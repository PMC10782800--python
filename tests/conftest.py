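"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ncwcluster.labels_io import MISSING, LabelMatrix


@pytest.fixture
def toy_matrix() -> LabelMatrix:
    """3 samples x 2 runs: [[1,1],[1,1],[2,NA]]."""
    labels = np.array([[1, 1], [1, 1], [2, MISSING]])
    return LabelMatrix(["s1", "s2", "s3"], ["r1", "r2"], labels)


def random_label_matrix(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_runs: int = 5,
    missing_frac: float = 0.3,
    max_label: int = 3,
) -> LabelMatrix:
    """Random matrix with missingness, regenerated until columns validate."""
    while True:
        labels = rng.integers(1, max_label + 1, size=(n_samples, n_runs))
        mask = rng.random((n_samples, n_runs)) < missing_frac
        labels = np.where(mask, MISSING, labels)
        if (labels != MISSING).sum(axis=0).min() >= 2:
            return LabelMatrix(
                [f"s{i}" for i in range(n_samples)],
                [f"r{j}" for j in range(n_runs)],
                labels,
            )


def brute_force_counts(m: LabelMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Triple-loop pair/run counting oracle for co-observation/co-assignment."""
    n, r = m.labels.shape
    together = np.zeros((n, n), dtype=int)
    observed = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            for c in range(r):
                a, b = m.labels[i, c], m.labels[j, c]
                if a != MISSING and b != MISSING:
                    observed[i, j] += 1
                    if a == b:
                        together[i, j] += 1
    return together, observed


def distinct_column_arrangements(column: np.ndarray) -> list[np.ndarray]:
    """All distinct placements of a column's observed labels (missing fixed)."""
    column = np.asarray(column)
    idx = np.nonzero(column != MISSING)[0]
    seen = set()
    out = []
    for perm in itertools.permutations(column[idx].tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        arr = column.copy()
        arr[idx] = perm
        out.append(arr)
    return out


def exhaustive_exceedance(m: LabelMatrix) -> tuple[np.ndarray, int]:
    """Exact per-pair exceedance counts over the full arrangement space.

    Enumerates every combination of distinct per-column arrangements
    (each equally likely under uniform within-column permutation) and counts
    combinations whose co-assignment count reaches the observed one.
    """
    obs_together, _ = brute_force_counts(m)
    per_col = [distinct_column_arrangements(m.labels[:, j])
               for j in range(m.n_runs)]
    n = m.n_samples
    exceed = np.zeros((n, n), dtype=np.int64)
    total = 0
    for combo in itertools.product(*per_col):
        grid = np.column_stack(combo)
        together = np.zeros((n, n), dtype=int)
        for c in range(grid.shape[1]):
            col = grid[:, c]
            obs = col != MISSING
            eq = (col[:, None] == col[None, :]) & obs[:, None] & obs[None, :]
            together += eq
        exceed += together >= obs_together
        total += 1
    return exceed, total
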