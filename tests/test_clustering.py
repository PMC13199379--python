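import numpy as np
import pytest
from dataclasses import replace

import rareq
from rareq.clustering import (ClusterAssignment, RareQParams, merge_clusters,
                              propagate, retain_rare, run_rareq, vote_refine)
from rareq.knn import EmbeddingMatrix, build_knn
from rareq.qmetric import ClusterStats, QScores, all_q, cluster_stats


def _assignment(labels, stage="voted"):
    return ClusterAssignment(labels=np.asarray(labels, dtype=np.int64),
                             stage=stage)


class TestPropagate:
    def test_two_blobs_give_disjoint_clusters(self):
        # two well-separated Gaussian blobs with interior Q maxima: no
        # propagated cluster spans both blobs
        emb, labels = rareq.make_blobs(rareq.BlobSpec(
            n_cells=60, proportions=(0.5, 0.5), separation=50.0,
            n_dims=3, seed=0))
        idx = build_knn(emb, 20)
        params = RareQParams()
        out = propagate(idx, all_q(idx, 6), params)
        assert out.stage == "propagated"
        left = set(np.unique(out.labels[labels == "type_0"]).tolist())
        right = set(np.unique(out.labels[labels == "type_1"]).tolist())
        assert left.isdisjoint(right)
        assert out.n_clusters < 60

    def test_uniform_clique_q_gives_singletons(self, hexpair_index):
        # perfect 6-cliques have Q = 1 everywhere: no strict improvement,
        # so every cell stays its own waypoint
        params = RareQParams(k=6, k_param=12)
        out = propagate(hexpair_index, all_q(hexpair_index, 6), params)
        assert out.n_clusters == 12

    def test_local_maximum_is_waypoint(self, line10_index_cap20):
        q = QScores(q=np.array([0.5, 0.9, 0.5, 0.5, 0.5,
                                0.5, 0.5, 0.5, 0.5, 0.5]), k=3)
        out = propagate(line10_index_cap20, q, RareQParams(k=3, k_param=10))
        assert 1 in out.waypoints
        assert out.labels[1] == 1

    def test_identical_q_everywhere_gives_singletons(self, line10_index_cap20):
        q = QScores(q=np.full(10, 0.7), k=3)
        out = propagate(line10_index_cap20, q, RareQParams(k=3, k_param=10))
        assert np.array_equal(out.labels, np.arange(10))
        assert len(out.waypoints) == 10

    def test_fixed_point_property(self, planted_blobs):
        emb, _ = planted_blobs
        idx = build_knn(emb, 20)
        params = RareQParams()
        q = all_q(idx, params.k)
        out = propagate(idx, q, params)
        assert out.converged
        # every label is a waypoint's own label
        assert set(np.unique(out.labels)) <= set(out.waypoints.tolist())

    def test_size_mismatch_raises(self, line10_index_cap20):
        q = QScores(q=np.ones(4), k=3)
        with pytest.raises(ValueError, match="inconsistent inputs"):
            propagate(line10_index_cap20, q, RareQParams(k=3, k_param=10))


class TestVoteRefine:
    def test_minority_cell_flips_to_neighborhood_majority(self,
                                                          hexpair_index):
        labels = np.zeros(12, dtype=np.int64)
        labels[6:] = 1
        labels[0] = 1  # mislabeled member of the first clique
        out = vote_refine(hexpair_index,
                          _assignment(labels, "propagated"),
                          RareQParams(k=6, k_param=12))
        assert out.labels[0] == 0
        assert out.stage == "voted"

    def test_separated_clusters_are_fixed_point(self, hexpair_index):
        labels = np.array([0] * 6 + [1] * 6)
        out = vote_refine(hexpair_index,
                          _assignment(labels, "propagated"),
                          RareQParams(k=6, k_param=12))
        assert np.array_equal(out.labels, labels)
        assert out.iterations_used == 1 and out.converged

    def test_exact_tie_keeps_current_label(self):
        # 4 cells in a row, vote_k=4: cell 1 sees labels {0,0,1,1} -> tie
        idx = build_knn(EmbeddingMatrix.from_coords(
            np.arange(4, dtype=float)[:, None]), 4)
        labels = np.array([0, 1, 0, 1])
        out = vote_refine(idx, _assignment(labels, "propagated"),
                          RareQParams(k=4, k_param=4, max_vote_rounds=1))
        # cell 1's neighborhood [1,0,2,3] has two 0s and two 1s
        assert out.labels[1] == 1

    def test_partition_preserved(self, planted_result):
        result, _ = planted_result
        assert result.labels.shape[0] == 2_000
        assert np.all(result.labels >= 0)


class TestRetainRare:
    def test_strict_threshold(self):
        stats = [ClusterStats(i, np.arange(1), 1, 1, 1.0, mq)
                 for i, mq in enumerate([0.9, 0.61, 0.6, 0.3])]
        assert retain_rare(stats, 0.6) == {0, 1}

    def test_empty_and_all(self):
        assert retain_rare([], 0.6) == set()
        stats = [ClusterStats(i, np.arange(1), 1, 1, 1.0, 1.0)
                 for i in range(3)]
        assert retain_rare(stats, 0.6) == {0, 1, 2}


class TestMergeClusters:
    def test_bisected_blob_remerges(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((400, 5))
        idx = build_knn(EmbeddingMatrix.from_coords(coords), 20)
        labels = np.zeros(400, dtype=np.int64)
        labels[200:] = 1
        out = merge_clusters(idx, _assignment(labels), set(), RareQParams())
        assert out.n_clusters == 1
        assert out.stage == "merged"

    def test_disconnected_blobs_never_merge(self):
        rng = np.random.default_rng(1)
        coords = np.concatenate([rng.standard_normal((100, 5)),
                                 rng.standard_normal((100, 5)) + 1000.0])
        idx = build_knn(EmbeddingMatrix.from_coords(coords), 20)
        labels = np.array([0] * 100 + [1] * 100, dtype=np.int64)
        out = merge_clusters(idx, _assignment(labels), set(), RareQParams())
        assert out.n_clusters == 2

    def test_rare_clusters_frozen(self):
        rng = np.random.default_rng(2)
        coords = rng.standard_normal((400, 5))
        idx = build_knn(EmbeddingMatrix.from_coords(coords), 20)
        labels = np.zeros(400, dtype=np.int64)
        labels[200:] = 1
        out = merge_clusters(idx, _assignment(labels), {0, 1}, RareQParams())
        assert out.n_clusters == 2  # both halves retained, untouched

    def test_singleton_survives_strict_conditions(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((100, 3))
        idx = build_knn(EmbeddingMatrix.from_coords(coords), 20)
        labels = np.zeros(100, dtype=np.int64)
        labels[0] = 1  # singleton: Q_c = 1, union can never exceed it
        out = merge_clusters(idx, _assignment(labels), set(), RareQParams())
        assert out.n_clusters == 2

    def test_min_cluster_size_absorbs_singleton(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((100, 3))
        idx = build_knn(EmbeddingMatrix.from_coords(coords), 20)
        labels = np.zeros(100, dtype=np.int64)
        labels[0] = 1
        out = merge_clusters(idx, _assignment(labels), set(),
                             RareQParams(min_cluster_size=2))
        assert out.n_clusters == 1

    def test_unknown_rare_id_raises(self, line10_index_cap20):
        with pytest.raises(ValueError, match="invalid rare set"):
            merge_clusters(line10_index_cap20,
                           _assignment(np.zeros(10)), {5},
                           RareQParams(k=3, k_param=10))


class TestRunRareq:
    def test_planted_rare_blob_recovered_exactly(self, planted_result):
        result, labels = planted_result
        part = rareq.LabeledPartition(predicted=result.labels, truth=labels)
        p, r, f1 = rareq.rare_prf(part, "type_1")
        assert (p, r, f1) == (1.0, 1.0, 1.0)
        # every cluster holding rare cells is pure and rare-flagged
        for cid in np.unique(result.labels[labels == "type_1"]):
            members = result.labels == cid
            assert set(labels[members]) == {"type_1"}
            assert int(cid) in result.rare_cluster_ids

    def test_rare_clusters_exceed_q_threshold(self, planted_result):
        result, _ = planted_result
        by_id = {s.cluster_id: s for s in result.cluster_stats}
        for cid in result.rare_cluster_ids:
            assert by_id[cid].mean_q > result.params.q_threshold

    def test_median_f1_one_over_seeds(self):
        f1s = []
        for seed in range(10):
            emb, labels = rareq.make_blobs(rareq.BlobSpec(seed=seed))
            res = run_rareq(emb)
            part = rareq.LabeledPartition(predicted=res.labels, truth=labels)
            f1s.append(rareq.rare_prf(part, "type_1")[2])
        assert np.median(f1s) == 1.0

    def test_zero_separation_collapses_f1(self):
        emb, labels = rareq.make_blobs(rareq.BlobSpec(separation=0.0,
                                                      seed=42))
        res = run_rareq(emb)
        part = rareq.LabeledPartition(predicted=res.labels, truth=labels)
        assert rareq.rare_prf(part, "type_1")[2] < 0.5

    def test_determinism(self, planted_blobs):
        emb, _ = planted_blobs
        a = run_rareq(emb)
        b = run_rareq(emb)
        assert np.array_equal(a.labels, b.labels)
        assert a.rare_cluster_ids == b.rare_cluster_ids

    def test_permutation_leaves_rare_recovery_invariant(self):
        # Q takes discrete values, so index tie-breaks legitimately shift
        # fragment boundaries under relabeling; the rare-cell set must
        # still be recovered identically
        emb, labels = rareq.make_blobs(rareq.BlobSpec(seed=5))
        rng = np.random.default_rng(6)
        perm = rng.permutation(emb.n_cells)
        a = run_rareq(emb)
        b = run_rareq(EmbeddingMatrix.from_coords(emb.coords[perm]))
        assert np.array_equal(a.is_rare()[perm], b.is_rare())

    def test_final_labels_contiguous(self, planted_result):
        result, _ = planted_result
        uniq = np.unique(result.labels)
        assert np.array_equal(uniq, np.arange(uniq.shape[0]))

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match="insufficient cells"):
            run_rareq(np.zeros((3, 2)) + np.arange(3)[:, None])

    def test_accepts_prebuilt_index(self, planted_blobs):
        emb, _ = planted_blobs
        idx = build_knn(emb, 20)
        a = run_rareq(idx)
        b = run_rareq(emb)
        assert np.array_equal(a.labels, b.labels)
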