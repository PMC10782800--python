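"""Resampling consensus clustering: fixed points, summaries, k selection."""

from __future__ import annotations

import numpy as np
import pytest

from ncwcluster.consensus import (
    ConsensusRunConfig,
    consensus_cluster_ncw,
    item_and_cluster_consensus,
)
from ncwcluster.simulate import SyntheticSpec, generate_cohort, nmi
from ncwcluster.ncw import compute_ncw


def block_matrix(sizes):
    """Exact 0/1 block-diagonal similarity for given cluster sizes."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return (labels[:, None] == labels[None, :]).astype(float), labels + 1


def test_perfect_two_block_fixed_point():
    S, truth = block_matrix([3, 3])
    cfg = ConsensusRunConfig(maxK=2, reps=1, p_item=1.0, seed=0)
    res = consensus_cluster_ncw(S, cfg)
    np.testing.assert_array_equal(res.per_k[2].consensus_matrix, S)
    assert nmi(res.per_k[2].consensus_class, truth) == 1.0


def test_full_subsampling_gives_binary_and_reps_invariant_consensus():
    S, _ = block_matrix([4, 3, 3])
    cfg1 = ConsensusRunConfig(maxK=4, reps=1, p_item=1.0, seed=0)
    cfg3 = ConsensusRunConfig(maxK=4, reps=3, p_item=1.0, seed=99)
    r1 = consensus_cluster_ncw(S, cfg1)
    r3 = consensus_cluster_ncw(S, cfg3)
    for k in (2, 3, 4):
        M = r1.per_k[k].consensus_matrix
        assert np.isin(M, [0.0, 1.0]).all()
        np.testing.assert_array_equal(M, r3.per_k[k].consensus_matrix)


def test_consensus_matrix_invariants_under_subsampling():
    rng = np.random.default_rng(4)
    S = rng.random((12, 12))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    cfg = ConsensusRunConfig(maxK=4, reps=30, p_item=0.7, seed=2)
    res = consensus_cluster_ncw(S, cfg)
    for k, kr in res.per_k.items():
        M = kr.consensus_matrix
        np.testing.assert_array_equal(M, M.T)
        np.testing.assert_array_equal(np.diag(M), np.ones(12))
        assert (M >= 0).all() and (M <= 1).all()
        assert len(set(kr.consensus_class.tolist())) == k


def test_maxk_bounds():
    S, _ = block_matrix([3, 3])
    with pytest.raises(ValueError, match="maxK"):
        consensus_cluster_ncw(S, ConsensusRunConfig(maxK=6, seed=0))
    with pytest.raises(ValueError):
        ConsensusRunConfig(maxK=1)


def test_undefined_entries_rejected():
    S = np.eye(4)
    S[0, 1] = S[1, 0] = np.nan
    with pytest.raises(ValueError, match="undefined"):
        consensus_cluster_ncw(S, ConsensusRunConfig(maxK=2, seed=0))


class TestCdfAndDelta:
    def test_all_ones_consensus_matrix_has_zero_area(self):
        # the CDF of an all-ones consensus matrix is a step at 1, whose
        # left Riemann area over [0, 1] is 0
        from ncwcluster.consensus import (
            ConsensusResult, KResult, consensus_cdf_and_delta)
        M = np.ones((6, 6))
        kr = KResult(M, np.zeros((5, 4)), np.array([1, 1, 1, 2, 2, 2]))
        res = ConsensusResult(per_k={2: kr},
                              config=ConsensusRunConfig(maxK=2, seed=0),
                              sample_ids=[f"s{i}" for i in range(6)])
        consensus_cdf_and_delta(res)
        assert res.area[2] == 0.0
        assert res.cdf[2][-1] == 1.0

    def test_cdf_monotone_zero_to_one(self):
        rng = np.random.default_rng(8)
        S = rng.random((10, 10))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        res = consensus_cluster_ncw(
            S, ConsensusRunConfig(maxK=5, reps=20, p_item=0.8, seed=1))
        for c in res.cdf.values():
            assert (np.diff(c) >= 0).all()
            assert c[-1] == 1.0

    def test_three_block_structure_selects_k3(self):
        S, _ = block_matrix([8, 8, 8])
        cfg = ConsensusRunConfig(maxK=6, reps=50, p_item=0.8, seed=0)
        res = consensus_cluster_ncw(S, cfg)
        assert res.chosen_k == 3
        assert res.delta_area[3] == max(
            res.delta_area[k] for k in range(3, 7))

    def test_areas_non_decreasing_in_k(self):
        for seed in range(20):
            cohort = generate_cohort(SyntheticSpec(
                n_samples=24, k_true=3, n_runs=15, noise_rate=0.15,
                coverage_range=(0.5, 1.0), seed=seed))
            ncw = compute_ncw(cohort.matrix, nperm_blocks=2, seed=seed,
                              unobserved_policy="zero")
            res = consensus_cluster_ncw(
                ncw, ConsensusRunConfig(maxK=5, reps=25, p_item=0.8,
                                        seed=seed))
            areas = [res.area[k] for k in sorted(res.area)]
            assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_elbow_threshold_selection(self):
        S, _ = block_matrix([8, 8, 8])
        cfg = ConsensusRunConfig(maxK=6, reps=50, p_item=0.8, seed=0,
                                 elbow_threshold=0.05)
        res = consensus_cluster_ncw(S, cfg)
        assert res.chosen_k >= 3


class TestItemAndClusterConsensus:
    def test_perfect_two_block_values(self):
        S, truth = block_matrix([3, 3])
        cfg = ConsensusRunConfig(maxK=2, reps=1, p_item=1.0, seed=0)
        res = consensus_cluster_ncw(S, cfg)
        cc = res.cluster_consensus.query("k == 2")
        assert (cc["value"] == 1.0).all()
        ic = res.item_consensus.query("k == 2")
        for _, row in ic.iterrows():
            i = res.sample_ids.index(row["sample"])
            own = truth[i] == res.per_k[2].consensus_class[
                res.sample_ids.index(row["sample"])]
            expected = 1.0 if (
                res.per_k[2].consensus_class[i] == row["cluster"]
            ) else 0.0
            assert row["value"] == expected

    def test_singleton_cluster_convention(self):
        # three distinct points: at k=3 each cluster is a singleton pair-wise
        S = np.eye(3)
        cfg = ConsensusRunConfig(maxK=2, reps=1, p_item=1.0, seed=0)
        res = consensus_cluster_ncw(S, cfg)
        cls = res.per_k[2].consensus_class
        sizes = np.bincount(cls)[1:]
        cc = res.cluster_consensus.query("k == 2")
        for _, row in cc.iterrows():
            if sizes[int(row["cluster"]) - 1] == 1:
                assert row["value"] == 0.0

    def test_matches_pair_averaging_oracle(self):
        rng = np.random.default_rng(3)
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        res = consensus_cluster_ncw(
            S, ConsensusRunConfig(maxK=3, reps=10, p_item=0.9, seed=0))
        item_and_cluster_consensus(res)
        for k, kr in res.per_k.items():
            M, cls = kr.consensus_matrix, kr.consensus_class
            for c in sorted(set(cls.tolist())):
                members = np.nonzero(cls == c)[0]
                # independent double-loop oracle
                vals = [M[i, j] for i in members for j in members if i < j]
                expected = float(np.mean(vals)) if vals else 0.0
                got = res.cluster_consensus.query(
                    "k == @k and cluster == @c")["value"].iloc[0]
                assert got == pytest.approx(expected)
                for i in range(6):
                    others = [j for j in members if j != i]
                    exp_i = float(np.mean([M[i, j] for j in others])) \
                        if others else 0.0
                    sid = res.sample_ids[i]
                    got_i = res.item_consensus.query(
                        "k == @k and cluster == @c and sample == @sid"
                    )["value"].iloc[0]
                    assert got_i == pytest.approx(exp_i)


@pytest.mark.parametrize("alg", ["hierarchical", "spectral", "kmedoids"])
def test_inner_algorithms_recover_clear_blocks(alg):
    S, truth = block_matrix([6, 6, 6])
    cfg = ConsensusRunConfig(maxK=4, reps=20, p_item=0.8, inner_alg=alg,
                             seed=1)
    res = consensus_cluster_ncw(S, cfg)
    assert nmi(res.per_k[3].consensus_class, truth) == 1.0


def test_synthetic_ncw_recovery_at_k3():
    cohort = generate_cohort(SyntheticSpec(
        n_samples=36, k_true=3, n_runs=20, noise_rate=0.1,
        coverage_range=(0.5, 1.0), seed=7))
    ncw = compute_ncw(cohort.matrix, nperm_blocks=3, seed=7)
    res = consensus_cluster_ncw(
        ncw, ConsensusRunConfig(maxK=6, reps=50, p_item=0.8, seed=7))
    assert nmi(res.per_k[3].consensus_class, cohort.truth) == 1.0
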