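from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scanclust import (
    align_labels,
    apply_permutation,
    center_stability,
    classification_metrics,
    confusion_matrix,
    cross_solution_agreement,
    kmeans_cluster,
    representativeness,
    scree,
)


def exhaustive_two_partition_wss(X):
    """Oracle: minimum within-cluster SS over all 2-partitions of the points."""
    n = len(X)
    best = np.inf
    # enumerate all subsets of points 1..n-1 as group B; point 0 stays in A
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.zeros(n, dtype=bool)
        for i in range(1, n):
            mask[i] = (mask_bits >> (i - 1)) & 1
        wss = 0.0
        for grp in (X[mask], X[~mask]):
            wss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestKmeansCluster:
    def test_two_point_masses_perfectly_separated(self, rng):
        va, vb = np.zeros(36), np.ones(36)
        X = np.vstack([np.tile(va, (48, 1)), np.tile(vb, (48, 1))])
        sol = kmeans_cluster(X, k=2, seed=0)
        assert sol.wss == pytest.approx(0.0)
        centers = sorted(sol.centers.tolist())
        assert np.allclose(centers[0], va) and np.allclose(centers[1], vb)
        assert len(set(sol.assignments[:48])) == 1
        assert set(sol.assignments[:48]) != set(sol.assignments[48:])

    def test_k1_center_is_mean_and_wss_is_total_ss(self, rng):
        X = rng.random((30, 4))
        sol = kmeans_cluster(X, k=1, seed=0)
        assert np.allclose(sol.centers[0], X.mean(axis=0))
        assert sol.wss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_deterministic_per_seed(self, rng):
        X = rng.random((40, 6))
        a = kmeans_cluster(X, k=3, seed=5)
        b = kmeans_cluster(X, k=3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.centers, b.centers)

    def test_fewer_vectors_than_k_raises(self, rng):
        with pytest.raises(ValueError, match="cannot fit"):
            kmeans_cluster(rng.random((2, 3)), k=3, seed=0)

    def test_too_few_distinct_vectors_raises(self):
        X = np.vstack([np.zeros(3)] * 5 + [np.ones(3)] * 5)
        with pytest.raises(ValueError, match="distinct"):
            kmeans_cluster(X, k=3, seed=0)

    def test_assignments_are_nearest_centers(self, rng):
        X = rng.random((50, 8))
        sol = kmeans_cluster(X, k=4, seed=1)
        dists = np.linalg.norm(X[:, None, :] - sol.centers[None], axis=2)
        assert np.array_equal(sol.assignments, dists.argmin(axis=1) + 1)

    def test_matches_exhaustive_partition_oracle(self, rng):
        # small enough to enumerate every 2-partition
        for trial in range(5):
            X = rng.random((8, 3))
            sol = kmeans_cluster(X, k=2, seed=trial, n_init=64)
            assert sol.wss == pytest.approx(exhaustive_two_partition_wss(X), rel=1e-9)


class TestScree:
    def test_two_point_masses(self):
        X = np.vstack([np.tile(np.zeros(4), (5, 1)), np.tile(np.ones(4), (5, 1))])
        out = dict(scree(X, k_max=2, seed=0))
        assert out[1] > 0 and out[2] == pytest.approx(0.0)

    def test_wss_non_increasing_in_k(self, rng):
        X = rng.random((40, 5))
        wss = [w for _, w in scree(X, k_max=6, seed=0, n_init=10)]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))


class TestAlignLabels:
    @pytest.mark.parametrize(
        "confusion,expected",
        [
            ([[8, 2], [1, 9]], [1, 2]),  # diagonal dominates: keep
            ([[2, 8], [9, 1]], [2, 1]),  # off-diagonal dominates: swap
            ([[5, 5], [5, 5]], [1, 2]),  # tie: keep by convention
        ],
    )
    def test_two_cluster_rule(self, confusion, expected):
        assert align_labels(np.array(confusion)).tolist() == expected

    def test_three_cluster_optimal_assignment(self):
        C = np.array([[0, 10, 0], [0, 0, 10], [10, 0, 0]])
        perm = align_labels(C)
        aligned = confusion_matrix(
            [1] * 10 + [2] * 10 + [3] * 10,
            apply_permutation([2] * 10 + [3] * 10 + [1] * 10, perm),
            k=3,
        )
        assert np.trace(aligned) == 30

    def test_non_square_raises(self):
        with pytest.raises(ValueError, match="square"):
            align_labels(np.zeros((2, 3)))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_aligned_two_cluster_accuracy_at_least_half(self, entries):
        C = np.array(entries).reshape(2, 2)
        if C.sum() == 0:
            return
        perm = align_labels(C)
        aligned = C[:, np.argsort(perm)]
        assert np.trace(aligned) / C.sum() >= 0.5


class TestClassificationMetrics:
    def test_arithmetic(self):
        m = classification_metrics(np.array([[45, 5], [3, 47]]))
        assert m.total_accuracy == pytest.approx(0.92)
        assert m.per_class_accuracy == pytest.approx([0.90, 0.94])
        assert m.estimated_proportions == pytest.approx([0.48, 0.52])

    def test_diagonal_matrix_is_perfect(self):
        m = classification_metrics(np.diag([10, 20]))
        assert m.total_accuracy == 1.0

    def test_absent_class_reported_missing(self):
        m = classification_metrics(np.array([[15, 5], [0, 0]]))
        assert np.isnan(m.per_class_accuracy[1])
        assert m.per_class_accuracy[0] == pytest.approx(0.75)

    def test_proportions_sum_to_one(self, rng):
        C = rng.integers(0, 20, size=(3, 3))
        C[0, 0] += 1
        m = classification_metrics(C)
        assert m.estimated_proportions.sum() == pytest.approx(1.0)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics(np.zeros((2, 2)))


class TestCenterStability:
    def test_identical_centers_correlate_perfectly(self, rng):
        centers = rng.random((2, 36))
        out = center_stability([centers] * 4)
        for c in (1, 2):
            assert np.allclose(out[c]["correlations"], 1.0)

    def test_affine_transform_preserves_correlation(self, rng):
        c = rng.random((2, 36))
        out = center_stability([c, 0.3 + 2.0 * c])
        assert out[1]["median"] == pytest.approx(1.0)
        assert out[2]["median"] == pytest.approx(1.0)

    def test_constant_center_reported_missing(self, rng):
        flat = np.vstack([np.full(36, 0.5), rng.random(36)])
        varied = rng.random((2, 36))
        out = center_stability([flat, varied])
        assert out[1]["n_undefined"] == 1
        assert out[2]["n_undefined"] == 0

    def test_needs_two_replicates(self, rng):
        with pytest.raises(ValueError, match="2 replicates"):
            center_stability([rng.random((2, 4))])


class TestRepresentativeness:
    def test_vector_at_center(self):
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert representativeness(np.zeros(2), centers) == pytest.approx([0.0, 1.0])

    def test_equidistant_vector(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert representativeness(np.array([1.0, 0.0]), centers) == pytest.approx(
            [0.5, 0.5]
        )

    def test_three_cluster_arithmetic(self):
        centers = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 0.0]])
        scores = representativeness(np.zeros(2), centers)
        assert scores == pytest.approx([0.25, 0.25, 0.5])

    def test_scores_sum_to_one(self, rng):
        centers = rng.random((4, 9))
        scores = representativeness(rng.random(9), centers)
        assert scores.sum() == pytest.approx(1.0)

    def test_all_centers_coincide_is_a_tie(self):
        centers = np.zeros((2, 3))
        assert np.isnan(representativeness(np.zeros(3), centers)).all()

    def test_exclusive_denominator_variant(self):
        centers = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 0.0]])
        scores = representativeness(np.zeros(2), centers, include_own=False)
        assert scores == pytest.approx([1 / 3, 1 / 3, 1.0])


class TestCrossSolutionAgreement:
    def test_identical_solutions(self, rng):
        X = rng.random((30, 6))
        a = kmeans_cluster(X, k=2, seed=0)
        table, agreement = cross_solution_agreement(a, a)
        assert agreement == 1.0
        assert np.all(table[~np.eye(2, dtype=bool)] == 0)

    def test_permuted_labels_still_agree(self, rng):
        X = rng.random((30, 6))
        a = kmeans_cluster(X, k=2, seed=0)
        b = a.relabel(np.array([2, 1]))
        _, agreement = cross_solution_agreement(a, b)
        assert agreement == 1.0

    def test_two_vs_three_cluster_tabulation(self, rng):
        # oracle: direct tabulation of joint assignments
        X = rng.random((60, 6))
        a = kmeans_cluster(X, k=2, seed=0)
        b = kmeans_cluster(X, k=3, seed=0)
        table, _ = cross_solution_agreement(a, b)
        expected = np.zeros((2, 3), dtype=int)
        for ai, bi in zip(a.assignments, b.assignments):
            expected[ai - 1, bi - 1] += 1
        assert np.array_equal(table, expected)
        assert table.sum() == 60
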