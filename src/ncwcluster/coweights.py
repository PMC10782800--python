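"""Missingness-aware pairwise consensus weights (co-association matrix).

For every pair of samples the classical consensus weight (CW) is the
fraction of clustering runs in which the two samples share a cluster.  With
unequal sample coverage the denominator matters: dividing by the *total*
number of runs silently converts shared missingness into similarity.  Here
the denominator is restricted to runs in which *both* samples are observed
(pairwise-available-case), so CW is the conditional co-clustering rate given
co-observation.  Pairs never co-observed have no defined CW and are carried
as an explicit NaN marker, never imputed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .labels_io import LabelMatrix


@dataclasses.dataclass
class CoClusterCounts:
    """Sufficient statistics for the consensus weights of one label matrix.

    ``together[i, j]`` counts runs where samples i and j are both observed
    and share a label; ``observed[i, j]`` counts runs where both are
    observed.  Diagonals hold each sample's own observation count (a sample
    trivially co-clusters with itself wherever it is observed).
    """

    together: np.ndarray
    observed: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.together.shape != self.observed.shape:
            raise ValueError("together/observed shape mismatch")
        if (self.together > self.observed).any():
            raise ValueError("together may not exceed observed")


@dataclasses.dataclass
class CWMatrix:
    """Symmetric pairwise consensus-weight matrix in [0, 1].

    ``values[i, j]`` is NaN where the pair was never co-observed; the
    diagonal is 1 by definition.
    """

    values: np.ndarray
    sample_ids: list[str]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def encode_labels(m: LabelMatrix) -> np.ndarray:
    """Integer grid where missing cells get a row-unique negative code.

    With this encoding two cells are equal iff both are observed with the
    same label *or* they belong to the same sample, so pairwise equality
    counts need no separate observation mask off the diagonal.
    """
    n = m.n_samples
    codes = -(np.arange(n, dtype=np.int64) + 1)[:, None]
    return np.where(m.observed, m.labels, codes)


def cocluster_counts(m: LabelMatrix) -> CoClusterCounts:
    """Count co-observation and co-assignment for every sample pair."""
    obs = m.observed.astype(np.int64)
    observed = obs @ obs.T
    enc = encode_labels(m)
    # (n, n, r) boolean broadcast; chunk over runs to bound memory for wide
    # matrices (hundreds of runs).
    n, r = enc.shape
    together = np.zeros((n, n), dtype=np.int64)
    step = max(1, int(4e7 // (n * n)) or 1)
    for start in range(0, r, step):
        block = enc[:, start : start + step]
        together += (block[:, None, :] == block[None, :, :]).sum(axis=2)
    np.fill_diagonal(together, np.diag(observed))
    return CoClusterCounts(together, observed, list(m.sample_ids))


def consensus_weights(c: CoClusterCounts) -> CWMatrix:
    """Elementwise ``together / observed``; NaN where never co-observed."""
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(
            c.observed > 0, c.together / np.maximum(c.observed, 1), np.nan
        )
    np.fill_diagonal(values, 1.0)
    return CWMatrix(values, list(c.sample_ids))


def cw_from_matrix(m: LabelMatrix) -> CWMatrix:
    """Convenience: consensus weights straight from a label matrix."""
    return consensus_weights(cocluster_counts(m))


def write_cw(cw: CWMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cw.values, index=cw.sample_ids, columns=cw.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
              float_format="%.10g")


def read_symmetric_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square sample x sample TSV (as written by this package)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path} is not a symmetric sample x sample matrix")
    return df.to_numpy(dtype=float), list(df.index.astype(str))
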