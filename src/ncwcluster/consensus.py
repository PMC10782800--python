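"""Resampling consensus clustering of the NCW matrix.

The final partition is obtained Monti-style: for each candidate number of
clusters k, the samples are repeatedly subsampled, the chosen inner
algorithm is run on the induced NCW submatrix (as distance ``1 - NCW`` for
hierarchical and k-medoids, as affinity for spectral), and the consensus
matrix records, for every pair, the fraction of co-sampled iterations in
which the pair landed in the same cluster.  Cutting an agglomerative tree of
``1 - consensus`` at k yields the consensus class assignment; CDFs of the
consensus values and the relative increase of their area (delta area) drive
the choice of k.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import SpectralClustering

from .ncw import NCWResult

logger = logging.getLogger(__name__)

INNER_ALGS = ("hierarchical", "spectral", "kmedoids")
LINKAGES = ("average", "complete", "ward")

#: Evaluation grid for consensus-value CDFs.
CDF_GRID = np.linspace(0.0, 1.0, 101)


@dataclasses.dataclass(frozen=True)
class ConsensusRunConfig:
    """Settings for the resampling consensus step.

    maxK is the largest number of clusters evaluated (k runs 2..maxK);
    ``reps`` resampling iterations each draw ``ceil(p_item * n)`` samples
    without replacement.  ``elbow_threshold``, when set, switches k selection
    from the delta-area argmax to "largest k whose delta area exceeds the
    threshold".
    """

    maxK: int = 6
    reps: int = 100
    p_item: float = 0.8
    inner_alg: str = "hierarchical"
    linkage: str = "average"
    seed: int = 0
    elbow_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.maxK < 2:
            raise ValueError("maxK must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.p_item <= 1):
            raise ValueError("p_item must lie in (0, 1]")
        if self.inner_alg not in INNER_ALGS:
            raise ValueError(f"inner_alg must be one of {INNER_ALGS}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")


@dataclasses.dataclass
class KResult:
    """Consensus output for one k: matrix, merge tree, class assignment."""

    consensus_matrix: np.ndarray
    consensus_tree: np.ndarray  # scipy linkage matrix (merge list)
    consensus_class: np.ndarray  # labels in 1..k


@dataclasses.dataclass
class ConsensusResult:
    per_k: dict[int, KResult]
    config: ConsensusRunConfig
    sample_ids: list[str]
    cluster_consensus: pd.DataFrame | None = None
    item_consensus: pd.DataFrame | None = None
    cdf: dict[int, np.ndarray] | None = None
    area: dict[int, float] | None = None
    delta_area: dict[int, float] | None = None
    chosen_k: int | None = None


# ---------------------------------------------------------------------------
# Inner algorithms


def _hierarchical_labels(D: np.ndarray, k: int, method: str) -> np.ndarray:
    cond = squareform(D, checks=False)
    Z = linkage(cond, method=method)
    return cut_tree(Z, n_clusters=k).ravel()


def _spectral_labels(S: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    seed = int(rng.integers(2**31 - 1))
    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="kmeans",
    )
    with warnings.catch_warnings():
        # disconnected affinity graphs are legitimate for near-binary NCW
        warnings.simplefilter("ignore")
        return model.fit_predict(S)


def _kmedoids_labels(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded PAM-style k-medoids on a precomputed distance matrix.

    Initialization follows the k-medoids++ recipe (distance-proportional
    seeding); the swap phase alternates assignment and per-cluster medoid
    updates until stable.
    """
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d_near = D[:, medoids].min(axis=1)
        total = d_near.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; pick any non-medoid
            choices = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(choices)))
            continue
        medoids.append(int(rng.choice(n, p=d_near / total)))
    medoids = np.asarray(medoids)
    for _ in range(100):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[int(np.argmin(costs))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def _inner_labels(
    ncw: np.ndarray, idx: np.ndarray, k: int, cfg: ConsensusRunConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    sub = ncw[np.ix_(idx, idx)]
    if cfg.inner_alg == "spectral":
        return _spectral_labels(sub, k, rng)
    D = 1.0 - sub
    np.fill_diagonal(D, 0.0)
    if cfg.inner_alg == "hierarchical":
        return _hierarchical_labels(D, k, cfg.linkage)
    return _kmedoids_labels(D, k, rng)


# ---------------------------------------------------------------------------
# Main resampling loop


def consensus_cluster_ncw(
    ncw: Union[NCWResult, np.ndarray],
    cfg: ConsensusRunConfig,
    sample_ids: list[str] | None = None,
) -> ConsensusResult:
    """Consensus-cluster an NCW matrix over k = 2..maxK.

    Accepts either an :class:`~ncwcluster.ncw.NCWResult` or a plain
    symmetric similarity matrix in [0, 1] with no undefined entries.
    Deterministic given ``cfg.seed``.
    """
    if isinstance(ncw, NCWResult):
        S = np.asarray(ncw.ncw, dtype=float)
        sample_ids = sample_ids or list(ncw.sample_ids)
    else:
        S = np.asarray(ncw, dtype=float)
        sample_ids = sample_ids or [f"S{i + 1}" for i in range(S.shape[0])]
    n = S.shape[0]
    if np.isnan(S).any():
        raise ValueError("NCW matrix contains undefined entries")
    if cfg.maxK > n - 1:
        raise ValueError(f"maxK={cfg.maxK} exceeds n_samples-1={n - 1}")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_items = math.ceil(cfg.p_item * n)
    per_k: dict[int, KResult] = {}
    for k in range(2, cfg.maxK + 1):
        conn = np.zeros((n, n))
        samp = np.zeros((n, n))
        for _ in range(cfg.reps):
            idx = np.sort(rng.choice(n, size=n_items, replace=False))
            labels = _inner_labels(S, idx, k, cfg, rng)
            same = labels[:, None] == labels[None, :]
            conn[np.ix_(idx, idx)] += same
            samp[np.ix_(idx, idx)] += 1.0
        if (samp == 0).any() and cfg.p_item < 1:
            uncovered = int((np.triu(samp == 0, k=1)).sum())
            if uncovered:
                logger.warning(
                    "k=%d: %d pair(s) never co-sampled; consensus set to 0",
                    k, uncovered,
                )
        with np.errstate(invalid="ignore"):
            M = np.where(samp > 0, conn / np.maximum(samp, 1), 0.0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        Dm = 1.0 - M
        np.fill_diagonal(Dm, 0.0)
        Z = linkage(squareform(Dm, checks=False), method=cfg.linkage)
        cls = cut_tree(Z, n_clusters=k).ravel() + 1
        per_k[k] = KResult(M, Z, cls.astype(int))
        logger.info("consensus k=%d done (%s, reps=%d)", k, cfg.inner_alg,
                    cfg.reps)

    result = ConsensusResult(per_k=per_k, config=cfg, sample_ids=sample_ids)
    consensus_cdf_and_delta(result)
    item_and_cluster_consensus(result)
    return result


# ---------------------------------------------------------------------------
# Model selection and summaries


def consensus_cdf_and_delta(result: ConsensusResult) -> ConsensusResult:
    """Consensus-value CDFs, their areas, delta areas, and the chosen k.

    The area is a left Riemann sum of the empirical CDF over a fixed grid on
    [0, 1].  ``delta_area(2) = area(2)``; for k > 2 it is the relative
    increase over k-1.  By default the chosen k is the argmax of delta area
    over k >= 3 (ties broken toward smaller k); with an elbow threshold set
    it is the largest k whose delta area exceeds it.
    """
    cfg = result.config
    ks = sorted(result.per_k)
    cdf: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    delta: dict[int, float] = {}
    for k in ks:
        M = result.per_k[k].consensus_matrix
        vals = M[np.triu_indices_from(M, k=1)]
        c = (vals[:, None] <= CDF_GRID[None, :]).mean(axis=0)
        cdf[k] = c
        area[k] = float(np.sum(c[:-1] * np.diff(CDF_GRID)))
    for k in ks:
        if k == ks[0]:
            delta[k] = area[k]
        else:
            prev = area[k - 1]
            delta[k] = (area[k] - prev) / prev if prev > 0 else area[k]
    if cfg.elbow_threshold is not None:
        above = [k for k in ks if delta[k] > cfg.elbow_threshold]
        chosen = max(above) if above else ks[0]
    else:
        candidates = [k for k in ks if k >= 3] or ks
        best = max(delta[k] for k in candidates)
        chosen = min(k for k in candidates if delta[k] == best)
    result.cdf, result.area, result.delta_area = cdf, area, delta
    result.chosen_k = int(chosen)
    return result


def item_and_cluster_consensus(result: ConsensusResult) -> ConsensusResult:
    """Cluster-consensus and item-consensus tables for every k.

    Cluster consensus is the mean consensus over distinct within-cluster
    pairs (0 for singletons); item consensus of sample i toward cluster c is
    the mean consensus between i and the members of c other than i.
    """
    cluster_rows, item_rows = [], []
    for k in sorted(result.per_k):
        kr = result.per_k[k]
        M, cls = kr.consensus_matrix, kr.consensus_class
        for c in sorted(set(cls.tolist())):
            members = np.nonzero(cls == c)[0]
            if members.size >= 2:
                sub = M[np.ix_(members, members)]
                pair_mean = float(
                    sub[np.triu_indices(members.size, k=1)].mean()
                )
            else:
                pair_mean = 0.0
            cluster_rows.append({"k": k, "cluster": int(c), "value": pair_mean})
            for i in range(len(cls)):
                others = members[members != i]
                v = float(M[i, others].mean()) if others.size else 0.0
                item_rows.append(
                    {"k": k, "cluster": int(c),
                     "sample": result.sample_ids[i], "value": v}
                )
    result.cluster_consensus = pd.DataFrame(cluster_rows)
    result.item_consensus = pd.DataFrame(item_rows)
    return result
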