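"""Normalized consensus weights (NCW) by column-wise permutation testing.

The classical consensus weight (CW) of a sample pair cannot distinguish a
pair that co-clusters in 10 informative runs from one that co-clusters in 2
nearly-constant runs: both may score 1.0.  The NCW replaces the raw rate
with the strength of evidence against a permutation null.  Each column of
the label matrix is permuted independently, *keeping missing positions
fixed*, so the null preserves the per-run label composition and the exact
missingness pattern while destroying any sample-to-sample association.  For
each pair the one-sided empirical p-value

    P = (#{permutations with permuted CW >= observed CW} + 1) / (nperm + 1)

is computed against that pair's own permuted distribution, and

    NCW = 1 - P.

The add-one term is the standard finite-sample permutation estimator: it
keeps P > 0 (no impossibility claims from finite sampling) and hence
NCW < 1 strictly.  A pair co-observed only in constant-label columns always
ties its null (permuted CW = observed CW = 1), giving exceed = nperm and
NCW = 0 exactly — uninformative co-clustering carries no weight, which is
the correction the method exists for.

Permutations are organized in blocks (default 1000 elementary permutations
per block).  After every block the cumulative NCW estimate is snapshotted;
the squared differences between consecutive snapshots form a stability
trace whose per-block sum should shrink as the estimate converges, guiding
the choice of the number of permutations.

Randomness: one master seed spawns one child ``SeedSequence`` per block, so
blocks are independently reproducible and the result depends only on
``(matrix, seed, nperm_blocks, block_size)``.

Since missing positions never move, the co-observation counts (the CW
denominators) are permutation-invariant; only the co-assignment numerators
are recomputed per permutation, and "permuted CW >= observed CW" reduces to
an integer comparison of co-assignment counts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coweights import cocluster_counts, encode_labels
from .labels_io import MISSING, LabelMatrix

logger = logging.getLogger(__name__)

#: Elementary permutations per block.
BLOCK_SIZE: int = 1000


@dataclasses.dataclass
class StabilityTrace:
    """Squared NCW changes between consecutive permutation blocks.

    ``blocks[b]`` is the 1-based index of the later block (so entries exist
    for blocks 2..nperm_blocks); ``distances[b]`` holds the per-pair squared
    differences over defined upper-triangle pairs, ``sum_distance[b]`` their
    sum.
    """

    blocks: np.ndarray
    distances: list[np.ndarray]
    sum_distance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, d, s in zip(self.blocks, self.distances, self.sum_distance):
            q1, q2, q3 = np.percentile(d, [25, 50, 75]) if d.size else (0, 0, 0)
            rows.append(
                {"block": int(b), "sum_distance": s, "q1": q1, "median": q2,
                 "q3": q3, "max": d.max() if d.size else 0.0}
            )
        return pd.DataFrame(rows)


@dataclasses.dataclass
class NCWResult:
    """NCW matrix with its permutation bookkeeping.

    ``ncw`` is symmetric with unit diagonal and entries in [0, 1);
    ``exceed_counts[i, j]`` is the number of permutations whose permuted CW
    reached the observed CW of pair (i, j); ``total_perms`` is
    ``nperm_blocks * block_size``.
    """

    ncw: np.ndarray
    exceed_counts: np.ndarray
    total_perms: int
    stability: StabilityTrace
    seed: int
    sample_ids: list[str]


def permute_column(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly permute one column's observed labels among observed positions.

    Missing positions (:data:`~ncwcluster.labels_io.MISSING`) stay fixed; the
    multiset of observed labels is preserved.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    idx = np.nonzero(labels != MISSING)[0]
    out[idx] = labels[idx][rng.permutation(idx.size)]
    return out


def _permuted_exceed_block(
    enc: np.ndarray,
    obs_positions: list[np.ndarray],
    obs_labels: list[np.ndarray],
    obs_together: np.ndarray,
    rng: np.random.Generator,
    block_size: int,
) -> np.ndarray:
    """Exceedance counts contributed by one block of permutations.

    Permutations are drawn in chunks: for every column, a chunk of uniform
    keys is argsorted to reorder that column's observed labels (a uniform
    random permutation).  Co-assignment counts for the whole chunk are then
    accumulated with one boolean broadcast per chunk.
    """
    n, r = enc.shape
    exceed = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, min(block_size, int(2e7 // max(1, n * n * r))))
    done = 0
    while done < block_size:
        c = min(chunk, block_size - done)
        perm = np.broadcast_to(enc, (c, n, r)).copy()
        for j in range(r):
            pos, lab = obs_positions[j], obs_labels[j]
            order = np.argsort(rng.random((c, lab.size)), axis=1)
            perm[:, pos, j] = lab[order]
        together = (perm[:, :, None, :] == perm[:, None, :, :]).sum(axis=3)
        exceed += (together >= obs_together).sum(axis=0)
        done += c
    return exceed


def compute_ncw(
    m: LabelMatrix,
    nperm_blocks: int = 10,
    seed: int = 0,
    block_size: int = BLOCK_SIZE,
    unobserved_policy: str = "error",
) -> NCWResult:
    """Run the permutation test and assemble the NCW matrix.

    Parameters
    ----------
    m
        Validated label matrix.
    nperm_blocks
        Number of permutation blocks; total permutations are
        ``nperm_blocks * block_size``.
    seed
        Master seed; the result is a deterministic function of
        ``(m, nperm_blocks, seed, block_size)``.
    block_size
        Elementary permutations per block (default 1000).
    unobserved_policy
        What to do with pairs never co-observed: ``"error"`` (default)
        raises and points at coverage filtering; ``"zero"`` assigns NCW 0
        with a logged warning.
    """
    if nperm_blocks < 1:
        raise ValueError("nperm_blocks must be a positive integer")
    if unobserved_policy not in ("error", "zero"):
        raise ValueError("unobserved_policy must be 'error' or 'zero'")

    counts = cocluster_counts(m)
    n = m.n_samples
    offdiag = ~np.eye(n, dtype=bool)
    defined = (counts.observed > 0) & offdiag
    undefined = ~defined & offdiag
    if undefined.any():
        pairs = [
            (m.sample_ids[i], m.sample_ids[j])
            for i, j in zip(*np.nonzero(np.triu(undefined)))
        ]
        if unobserved_policy == "error":
            shown = ", ".join(f"{a}/{b}" for a, b in pairs[:10])
            more = "" if len(pairs) <= 10 else f" (+{len(pairs) - 10} more)"
            raise ValueError(
                f"{len(pairs)} sample pair(s) are never co-observed:"
                f" {shown}{more}; raise the coverage threshold"
                " (filter_by_coverage) or pass unobserved_policy='zero'"
            )
        logger.warning(
            "%d never-co-observed pair(s) assigned NCW 0", len(pairs)
        )

    enc = encode_labels(m)
    obs_positions = [np.nonzero(m.observed[:, j])[0] for j in range(m.n_runs)]
    obs_labels = [m.labels[obs_positions[j], j] for j in range(m.n_runs)]

    children = np.random.SeedSequence(seed).spawn(nperm_blocks)
    exceed = np.zeros((n, n), dtype=np.int64)
    snapshots: list[np.ndarray] = []
    for b, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        exceed += _permuted_exceed_block(
            enc, obs_positions, obs_labels, counts.together, rng, block_size
        )
        snap = _assemble_ncw(exceed, b * block_size, defined)
        snapshots.append(snap)
        logger.debug("block %d/%d done", b, nperm_blocks)

    total = nperm_blocks * block_size
    stability = stability_distances(snapshots)
    ncw = snapshots[-1].copy()
    if undefined.any():  # only reachable under the zero policy
        ncw[undefined] = 0.0
    logger.info(
        "NCW done: n=%d, runs=%d, perms=%d, defined pairs %.1f%%, "
        "final block stability sum %.3g",
        n, m.n_runs, total, 100 * defined.sum() / max(1, offdiag.sum()),
        stability.sum_distance[-1] if stability.sum_distance.size else 0.0,
    )
    return NCWResult(ncw, exceed, total, stability, seed, list(m.sample_ids))


def _assemble_ncw(exceed: np.ndarray, total: int, defined: np.ndarray) -> np.ndarray:
    """NCW = 1 - (exceed+1)/(total+1) on defined pairs; NaN elsewhere, diag 1."""
    ncw = np.full(exceed.shape, np.nan)
    ncw[defined] = 1.0 - (exceed[defined] + 1) / (total + 1)
    np.fill_diagonal(ncw, 1.0)
    return ncw


def stability_distances(snapshots: Sequence[np.ndarray]) -> StabilityTrace:
    """Per-block squared differences between consecutive cumulative NCWs.

    Distances are taken over upper-triangle entries defined (non-NaN) in the
    snapshots; block b compares snapshot b against snapshot b-1.
    """
    if len(snapshots) < 2:
        return StabilityTrace(np.array([], dtype=int), [], np.array([]))
    shape = snapshots[0].shape
    blocks, dists, sums = [], [], []
    for b in range(1, len(snapshots)):
        prev, cur = snapshots[b - 1], snapshots[b]
        if prev.shape != shape or cur.shape != shape:
            raise ValueError("stability snapshots have mismatched shapes")
        triu = np.triu(np.ones(shape, dtype=bool), k=1)
        mask = triu & ~np.isnan(prev) & ~np.isnan(cur)
        d = (cur[mask] - prev[mask]) ** 2
        blocks.append(b + 1)
        dists.append(d)
        sums.append(d.sum())
    return StabilityTrace(np.asarray(blocks), dists, np.asarray(sums))


def write_ncw(result: NCWResult, path: str | Path) -> None:
    df = pd.DataFrame(result.ncw, index=result.sample_ids,
                      columns=result.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
              float_format="%.10g")


def write_stability(result: NCWResult, path: str | Path) -> None:
    result.stability.to_frame().to_csv(path, sep="\t", index=False,
                                       float_format="%.10g")
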