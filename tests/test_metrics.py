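"""Tests for the evaluation metrics against brute-force oracles."""

import numpy as np
import pytest

from asrnet import (
    GroundTruthNetwork,
    align_global_mean,
    clustering_accuracy,
    icc_c1,
    modularity_communities,
    sensitivity,
    silhouette_similarity,
)

from conftest import brute_force_accuracy, brute_force_modularity


def random_association(rng, n):
    raw = np.abs(rng.normal(size=(n, n)))
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 0.0)
    return raw


class TestSensitivity:
    def _truth(self, n, directed_edges):
        adj = np.zeros((n, n), dtype=int)
        for i, j in directed_edges:
            adj[i, j] = 1
        return GroundTruthNetwork(adj, np.zeros(n, dtype=int))

    def test_perfect_separation_is_one(self):
        truth = self._truth(5, [(0, 1), (1, 2)])
        A = np.full((5, 5), 0.1)
        np.fill_diagonal(A, 0.0)
        A[0, 1] = A[1, 0] = 0.9
        A[1, 2] = A[2, 1] = 0.8
        assert sensitivity(A, truth) == 1.0

    def test_zero_matrix_scores_zero(self):
        truth = self._truth(5, [(0, 1), (1, 2)])
        assert sensitivity(np.zeros((5, 5)), truth) == 0.0

    def test_hand_computed_percentile_case(self):
        """5-node toy with one inflated false pair, checked by hand.

        True pairs (0,1) and (1,2) score 0.9 and 0.5; the 8 false pairs
        are 0.1 except (3,4)=0.6. Sorted FP: seven 0.1 then 0.6, and the
        interpolated q95 = 0.1 + (0.6-0.1)*(6.65-6) = 0.425. So 0.9 and
        0.5 both exceed it: sensitivity 1.0. With the nearest-rank q95
        (= 0.6) only 0.9 passes: 0.5.
        """
        truth = self._truth(5, [(0, 1), (1, 2)])
        A = np.full((5, 5), 0.1)
        np.fill_diagonal(A, 0.0)
        A[0, 1] = A[1, 0] = 0.9
        A[1, 2] = A[2, 1] = 0.5
        A[3, 4] = A[4, 3] = 0.6
        fp = np.array([0.1] * 7 + [0.6])
        q95 = np.percentile(fp, 95)
        assert q95 == pytest.approx(0.425)
        assert sensitivity(A, truth) == 1.0
        assert sensitivity(A, truth, percentile_method="nearest") == 0.5

    def test_direction_is_ignored(self):
        """A pair connected in either direction counts once."""
        t1 = self._truth(4, [(0, 1)])
        t2 = self._truth(4, [(1, 0)])
        t3 = self._truth(4, [(0, 1), (1, 0)])
        rng = np.random.default_rng(0)
        A = random_association(rng, 4)
        assert sensitivity(A, t1) == sensitivity(A, t2) == sensitivity(A, t3)
        assert t3.n_true_connections == 1

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(1)
        n = 6
        A = random_association(rng, n)
        adj = (rng.uniform(size=(n, n)) < 0.3).astype(int)
        np.fill_diagonal(adj, 0)
        truth = GroundTruthNetwork(adj, np.zeros(n, dtype=int))
        perm = rng.permutation(n)
        A_p = A[np.ix_(perm, perm)]
        truth_p = GroundTruthNetwork(adj[np.ix_(perm, perm)], np.zeros(n, dtype=int))
        assert sensitivity(A, truth) == pytest.approx(sensitivity(A_p, truth_p))

    def test_no_false_pairs_is_an_error(self):
        adj = np.ones((3, 3), dtype=int)
        np.fill_diagonal(adj, 0)
        truth = GroundTruthNetwork(adj, np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            sensitivity(np.zeros((3, 3)), truth)


class TestClusteringAccuracy:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert clustering_accuracy(labels, labels) == 1.0

    def test_renaming_invariance(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([5, 5, 9, 9, 1, 1])
        assert clustering_accuracy(pred, truth) == 1.0

    def test_hand_case_five_sixths(self):
        truth = np.array([0, 0, 0, 1, 1, 1])
        pred = np.array([2, 2, 1, 1, 1, 1])
        assert clustering_accuracy(pred, truth) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_bijection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        truth = rng.integers(0, 4, size=n)
        pred = rng.integers(0, 5, size=n)
        assert clustering_accuracy(pred, truth) == pytest.approx(
            brute_force_accuracy(pred, truth), abs=1e-12
        )

    def test_single_cluster_prediction_bound(self):
        truth = np.array([0, 0, 0, 1, 1, 2])
        pred = np.zeros(6, dtype=int)
        acc = clustering_accuracy(pred, truth)
        assert acc == pytest.approx(3 / 6)  # the largest true cluster share


class TestSilhouette:
    def test_block_similarity_closed_form(self):
        n = 6
        A = np.full((n, n), 0.1)
        A[:3, :3] = 0.9
        A[3:, 3:] = 0.9
        np.fill_diagonal(A, 0.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        s, s_mean = silhouette_similarity(A, labels)
        np.testing.assert_allclose(s, (0.9 - 0.1) / 0.9, atol=1e-12)
        assert s_mean == pytest.approx(8 / 9)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        A = random_association(rng, 8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, s1 = silhouette_similarity(A, labels)
        _, s2 = silhouette_similarity(3.7 * A, labels)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        A = np.array(
            [
                [0.0, 0.8, 0.3, 0.1],
                [0.8, 0.0, 0.2, 0.4],
                [0.3, 0.2, 0.0, 0.7],
                [0.1, 0.4, 0.7, 0.0],
            ]
        )
        labels = np.array([0, 0, 1, 1])
        s, _ = silhouette_similarity(A, labels)
        # node 0: a=0.8, b=mean(0.3,0.1)=0.2 -> (0.8-0.2)/0.8
        assert s[0] == pytest.approx(0.6 / 0.8)
        # node 2: a=0.7, b=mean(0.3,0.2)=0.25 -> (0.7-0.25)/0.7
        assert s[2] == pytest.approx(0.45 / 0.7)

    def test_singleton_cluster_scores_zero(self):
        rng = np.random.default_rng(3)
        A = random_association(rng, 5)
        labels = np.array([0, 0, 0, 0, 1])
        s, _ = silhouette_similarity(A, labels)
        assert s[4] == 0.0

    def test_single_cluster_is_an_error(self):
        rng = np.random.default_rng(4)
        A = random_association(rng, 4)
        with pytest.raises(ValueError):
            silhouette_similarity(A, np.zeros(4, dtype=int))


class TestAlignGlobalMean:
    def test_identical_matrices_unchanged(self):
        rng = np.random.default_rng(5)
        A = random_association(rng, 6)
        out = align_global_mean([A, A.copy()])
        np.testing.assert_allclose(out[0], A, atol=1e-12)
        np.testing.assert_allclose(out[1], A, atol=1e-12)

    def test_two_matrices_meet_in_the_middle(self):
        rng = np.random.default_rng(6)
        A = random_association(rng, 5)
        delta = 0.3
        n = 5
        B = A.copy()
        B[~np.eye(n, dtype=bool)] += 2 * delta * n * n / (n * n - n)
        out = align_global_mean([A, B])
        target = (A.mean() + B.mean()) / 2
        assert out[0].mean() == pytest.approx(target, abs=1e-12)
        assert out[1].mean() == pytest.approx(target, abs=1e-12)

    def test_global_means_equalized_and_diagonals_zero(self):
        rng = np.random.default_rng(7)
        mats = [random_association(rng, 7) for _ in range(3)]
        out = align_global_mean(mats)
        means = [m.mean() for m in out]
        assert np.ptp(means) < 1e-12
        for m in out:
            assert np.all(np.diag(m) == 0)


class TestModularity:
    def test_two_disconnected_cliques_q_half(self):
        n = 8
        A = np.zeros((n, n))
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        np.fill_diagonal(A, 0.0)
        q, labels, n_comm = modularity_communities(A, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert n_comm == 2

    def test_complete_graph_single_community_zero(self):
        """Under the degree-based null, one community over a uniform
        complete graph scores exactly zero."""
        import networkx as nx

        n = 6
        A = np.ones((n, n)) - np.eye(n)
        G = nx.from_numpy_array(A)
        q = nx.community.modularity(G, [set(range(n))], weight="weight")
        assert q == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        A = random_association(rng, n)
        # sprinkle some block structure so the optimum is non-trivial
        A[:3, :3] += 1.0
        A[3:, 3:] += 1.0
        np.fill_diagonal(A, 0.0)
        q, _, _ = modularity_communities(A, seed=0)
        assert q == pytest.approx(brute_force_modularity(A), abs=1e-9)

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity_communities(np.zeros((4, 4)))


class TestICC:
    def test_identical_sessions_score_one(self):
        data = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [3.0, 3.0]])
        assert icc_c1(data) == pytest.approx(1.0)

    def test_session_constant_shift_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(6, 3))
        shifted = data + np.array([10.0, -4.0, 2.5])
        assert icc_c1(data) == pytest.approx(icc_c1(shifted), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_anova_mean_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 5, 3
        data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
        # independent two-way ANOVA via design-matrix least squares
        grand = data.mean()
        ms_b = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        resid = (
            data
            - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True)
            + grand
        )
        ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
        expected = (ms_b - ms_e) / (ms_b + (k - 1) * ms_e)
        assert icc_c1(data) == pytest.approx(expected, abs=1e-10)

    def test_fixed_table_value(self):
        """4x2 table checked against a by-hand ANOVA decomposition."""
        data = np.array([[9.0, 10.0], [6.0, 7.0], [8.0, 8.0], [7.0, 9.0]])
        n, k = 4, 2
        grand = data.mean()
        ms_b = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        resid = (
            data
            - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True)
            + grand
        )
        ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
        assert icc_c1(data) == pytest.approx((ms_b - ms_e) / (ms_b + ms_e), abs=1e-10)

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            icc_c1(data)
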