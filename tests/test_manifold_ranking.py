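"""Bag metrics, affinity construction and the manifold-ranking solvers."""

import numpy as np
import pytest

from mrsmil.data_model import Bag, Instance
from mrsmil.manifold_ranking import (
    MRParams,
    affinity_from_distances,
    bag_distance,
    build_affinity,
    mr_classify,
    mr_rank,
    pairwise_bag_distances,
)

from conftest import vector_bag


class TestBagDistance:
    def test_identical_bags_distance_zero(self):
        a = vector_bag("a", [(1.0, 2.0), (3.0, 4.0)])
        assert bag_distance(a, a) == 0.0

    def test_singleton_bags_euclidean(self):
        a, b = vector_bag("a", [(0.0, 0.0)]), vector_bag("b", [(3.0, 4.0)])
        assert bag_distance(a, b) == pytest.approx(5.0)

    def test_min_hausdorff_takes_closest_pair(self):
        # brute force over the 2 cross pairs: min(5, sqrt(49+16)) = 5
        a = vector_bag("a", [(0.0, 0.0), (10.0, 0.0)])
        b = vector_bag("b", [(3.0, 4.0)])
        cross = [np.hypot(3 - x, 4 - y) for x, y in [(0, 0), (10, 0)]]
        assert bag_distance(a, b) == pytest.approx(min(cross)) == pytest.approx(5.0)

    def test_symmetry(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        for metric in ("min_hausdorff", "max_hausdorff", "average"):
            assert bag_distance(pos[0], neg[0], metric) == pytest.approx(
                bag_distance(neg[0], pos[0], metric)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            bag_distance(vector_bag("a", [(0.0,)]), vector_bag("b", [(0.0, 1.0)]))

    def test_pairwise_matches_scalar(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        bags = pos + neg
        D = pairwise_bag_distances(bags)
        for i in range(len(bags)):
            for j in range(len(bags)):
                assert D[i, j] == pytest.approx(bag_distance(bags[i], bags[j]))


class TestAffinity:
    def test_two_bags_kernel_value(self):
        # distance d with sigma=d -> off-diagonal exp(-1/2)
        a, b = vector_bag("a", [(0.0, 0.0)]), vector_bag("b", [(2.0, 0.0)])
        g = build_affinity([a, b], MRParams(sigma=2.0))
        assert g.W[0, 1] == pytest.approx(np.exp(-0.5))
        assert g.W[0, 0] == 0.0 and g.W[1, 1] == 0.0

    def test_zero_diagonal_and_symmetry(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        g = build_affinity(pos + neg, MRParams())
        np.testing.assert_allclose(np.diag(g.W), 0.0)
        np.testing.assert_allclose(g.W, g.W.T)
        assert np.all(g.W >= 0)

    def test_spectral_radius_at_most_one(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        g = build_affinity(pos + neg, MRParams())
        assert np.max(np.abs(np.linalg.eigvalsh(g.S))) <= 1.0 + 1e-12

    def test_permutation_equivariance(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        bags = pos + neg
        perm = [3, 1, 4, 0, 2, 9, 5, 8, 6, 7]
        g = build_affinity(bags, MRParams())
        gp = build_affinity([bags[i] for i in perm], MRParams())
        np.testing.assert_allclose(gp.W, g.W[np.ix_(perm, perm)], atol=1e-12)

    def test_degenerate_all_zero_distances(self):
        a = vector_bag("a", [(1.0, 1.0)])
        b = vector_bag("b", [(1.0, 1.0)])
        with pytest.raises(ValueError, match="degenerate"):
            build_affinity([a, b], MRParams(sigma="median"))


class TestMRRank:
    def test_alpha_to_zero_limit_keeps_seeds(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        g = build_affinity(pos + neg, MRParams())
        Y = np.zeros((10, 2))
        Y[0, 1] = Y[5, 0] = 1.0
        F = mr_rank(g, Y, MRParams(alpha=1e-12))
        np.testing.assert_allclose(F, Y, atol=1e-9)

    def test_three_node_path_hand_inverse(self):
        # path graph 0-1-2; seeds: node 0 -> class A, node 2 -> class B.
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        params = MRParams(alpha=0.8, sigma=1.0)
        g = affinity_from_distances(D, params)
        Y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        F = mr_rank(g, Y, params)
        expected = np.linalg.inv(np.eye(3) - params.alpha * g.S) @ Y
        np.testing.assert_allclose(F, expected, atol=1e-10)
        # symmetric construction: the middle node is exactly tied
        assert F[1, 0] == pytest.approx(F[1, 1])

    @pytest.mark.parametrize("alpha", [0.5, 0.9, 0.99])
    def test_solver_equivalence_random_graph(self, alpha):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
        params_cf = MRParams(alpha=alpha, sigma="median", solver="closed_form")
        params_it = MRParams(
            alpha=alpha, sigma="median", solver="iterative",
            max_iter=50_000, tol=1e-14,
        )
        g = affinity_from_distances(D, params_cf)
        Y = np.zeros((20, 2))
        Y[rng.choice(20, 3, replace=False), 0] = 1.0
        Y[rng.choice(20, 3, replace=False), 1] = 1.0
        F_cf = mr_rank(g, Y, params_cf)
        F_it = mr_rank(g, Y, params_it)
        assert np.max(np.abs(F_cf - F_it)) <= 1e-8

    def test_score_positivity(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        g = build_affinity(pos + neg, MRParams())
        Y = np.zeros((10, 2))
        Y[0, 1] = Y[5, 0] = 1.0
        F = mr_rank(g, Y, MRParams(alpha=0.9))
        assert np.all(F >= -1e-12)

    def test_permutation_equivariance_of_scores(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        bags = pos + neg
        params = MRParams(alpha=0.7)
        perm = np.array([2, 0, 1, 4, 3, 7, 9, 5, 6, 8])
        Y = np.zeros((10, 2))
        Y[0, 1] = Y[5, 0] = 1.0
        F = mr_rank(build_affinity(bags, params), Y, params)
        Fp = mr_rank(
            build_affinity([bags[i] for i in perm], params), Y[perm], params
        )
        np.testing.assert_allclose(Fp, F[perm], atol=1e-10)

    def test_knn_sparsified_solver(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        params = MRParams(alpha=0.5, knn=3)
        g = build_affinity(pos + neg, params)
        import scipy.sparse as sp

        assert sp.issparse(g.S)
        Y = np.zeros((10, 2))
        Y[0, 1] = Y[5, 0] = 1.0
        F = mr_rank(g, Y, params)
        assert F.shape == (10, 2) and np.all(np.isfinite(F))


class TestMRClassify:
    def test_query_identical_to_positive_reference(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        reference = [(pos[0], 1), (neg[0], 0)]
        pred = mr_classify(reference, [pos[0], neg[0]], MRParams())
        assert pred.tolist() == [1, 0]

    def test_two_separated_clusters(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        reference = [(pos[0], 1), (neg[0], 0)]
        pred = mr_classify(reference, list(pos[1:]) + list(neg[1:]), MRParams())
        assert pred.tolist() == [1] * 4 + [0] * 4

    def test_empty_query(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        pred = mr_classify([(pos[0], 1), (neg[0], 0)], [], MRParams())
        assert pred.shape == (0,)

    def test_single_class_reference_degenerate(self, two_cluster_bags):
        pos, neg = two_cluster_bags
        pred = mr_classify([(pos[0], 1), (pos[1], 1)], list(neg), MRParams())
        assert pred.tolist() == [1] * 5
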