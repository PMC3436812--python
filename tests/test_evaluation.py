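"""Nearest-neighbour error, baselines, GMM subclustering, distance tests."""

import numpy as np
import pytest
from scipy import integrate, stats

from stagemap.evaluation import (
    accuracy_up_to_swap,
    baseline_embedding,
    gmm_subclusters,
    min_distance_to_reference,
    nearest_neighbour_error,
    procrustes_align,
    subcluster_distance_test,
    subcluster_expression_profile,
)
from stagemap.exceptions import DegenerateInputError, InvalidInputError


class TestNearestNeighbourError:
    def test_well_separated_blobs_have_zero_errors(self):
        rng = np.random.default_rng(50)
        a = rng.normal(0.0, 0.1, size=(10, 2))
        b = rng.normal(50.0, 0.1, size=(10, 2))
        pts = np.vstack([a, b])
        labels = ["a"] * 10 + ["b"] * 10
        assert nearest_neighbour_error(pts, labels) == 0

    def test_alternating_collinear_points(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        labels = ["A", "B", "A", "B"]
        # ties resolve to the smallest index, so every neighbour differs
        assert nearest_neighbour_error(pts, labels) == 4

    def test_matches_double_loop(self):
        rng = np.random.default_rng(51)
        pts = rng.normal(size=(50, 3))
        labels = rng.integers(0, 4, size=50)
        errors = 0
        for i in range(50):
            best, best_d = None, np.inf
            for j in range(50):
                if j == i:
                    continue
                d = np.sqrt(np.sum((pts[i] - pts[j]) ** 2))
                if d < best_d:
                    best, best_d = j, d
            errors += labels[best] != labels[i]
        assert nearest_neighbour_error(pts, labels) == errors

    def test_invariant_under_similarity_transform(self):
        rng = np.random.default_rng(52)
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        transformed = 3.5 * pts @ R + np.array([10.0, -4.0])
        assert (nearest_neighbour_error(transformed, labels)
                == nearest_neighbour_error(pts, labels))

    def test_rejects_single_point(self):
        with pytest.raises(InvalidInputError):
            nearest_neighbour_error(np.zeros((1, 2)), ["a"])


class TestBaselineEmbedding:
    def test_pca_recovers_known_component_variances(self):
        rng = np.random.default_rng(53)
        n = 4000
        Y = rng.standard_normal((n, 4)) * np.sqrt([4.0, 1.0, 0.01, 0.01])
        Z = baseline_embedding(Y, "pca", q=2)
        v = Z.var(axis=0, ddof=1)
        assert v[0] == pytest.approx(4.0, rel=0.1)
        assert v[1] == pytest.approx(1.0, rel=0.1)

    def test_pca_deterministic(self):
        rng = np.random.default_rng(54)
        Y = rng.normal(size=(20, 5))
        assert np.array_equal(baseline_embedding(Y, "pca", 2),
                              baseline_embedding(Y, "pca", 2))

    def test_ica_recovers_uniform_sources(self):
        rng = np.random.default_rng(55)
        S = rng.uniform(-1, 1, size=(2000, 2))
        A = np.array([[1.0, 0.4], [0.3, 1.0], [0.5, -0.7]]).T  # 2 x 3 mixing
        Y = S @ A
        Z = baseline_embedding(Y, "ica", q=2, seed=0)
        corr = np.abs(np.corrcoef(S.T, Z.T)[:2, 2:])
        # each true source matches one recovered component almost perfectly
        assert corr.max(axis=1).min() > 0.99

    def test_ica_seeded_and_canonicalized(self):
        rng = np.random.default_rng(56)
        Y = rng.normal(size=(100, 4)) ** 3
        assert np.allclose(baseline_embedding(Y, "ica", 2, seed=3),
                           baseline_embedding(Y, "ica", 2, seed=3))

    def test_rank_deficient_padded_with_warning(self):
        t = np.linspace(0, 1, 15)[:, None]
        Y = t @ np.array([[1.0, -2.0, 0.5]])
        with pytest.warns(UserWarning, match="rank"):
            Z = baseline_embedding(Y, "pca", q=2)
        assert np.all(Z[:, 1] == 0)


class TestGMMSubclusters:
    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(57)
        a = rng.normal(0.0, 1.0, size=(20, 2))
        b = rng.normal(10.0, 1.0, size=(20, 2))  # 10 sigma apart
        truth = np.array([0] * 20 + [1] * 20)
        assign = gmm_subclusters(np.vstack([a, b]), seed=0)
        assert accuracy_up_to_swap(assign, truth) == 1.0

    def test_single_blob_runs_to_completion(self):
        rng = np.random.default_rng(58)
        assign = gmm_subclusters(rng.normal(size=(30, 2)), seed=0)
        assert set(np.unique(assign)) <= {0, 1}

    def test_mirrored_data_mirrors_assignment(self):
        rng = np.random.default_rng(59)
        pts = np.vstack([rng.normal(-2, 0.5, size=(15, 2)),
                         rng.normal(2, 0.5, size=(15, 2))])
        a1 = gmm_subclusters(pts, seed=1)
        a2 = gmm_subclusters(-pts, seed=1)
        assert accuracy_up_to_swap(a1, a2) == 1.0

    def test_accuracy_near_bayes_rate_at_two_sigma(self):
        # 1-D two-component mixture, means +/- 1, unit SD (2 sigma separation)
        rng = np.random.default_rng(60)
        n = 400
        truth = rng.integers(0, 2, size=n)
        pts = rng.normal(0.0, 1.0, size=(n, 1)) + (2.0 * truth - 1.0)[:, None]
        assign = gmm_subclusters(pts, seed=0)
        acc = accuracy_up_to_swap(assign, truth)
        # Bayes rate by numerical integration of the overlap of the densities
        f0 = lambda x: stats.norm.pdf(x, -1, 1)
        f1 = lambda x: stats.norm.pdf(x, 1, 1)
        err, _ = integrate.quad(lambda x: 0.5 * np.minimum(f0(x), f1(x)), -12, 12)
        assert acc >= (1.0 - err) - 0.05

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            gmm_subclusters(np.ones((20, 2)), seed=0)


class TestDistances:
    def test_identical_cell_has_zero_distance(self):
        Y = np.array([[1.0, 2.0, 3.0]])
        assert min_distance_to_reference(Y, Y)[0] == 0.0

    def test_three_four_five(self):
        cell = np.zeros((1, 5))
        cell[0, 0], cell[0, 1] = 3.0, 4.0
        ref = np.zeros((1, 5))
        assert min_distance_to_reference(cell, ref)[0] == pytest.approx(5.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(61)
        A = rng.normal(size=(7, 4))
        B = rng.normal(size=(9, 4))
        got = min_distance_to_reference(A, B)
        for i in range(7):
            expected = min(np.sqrt(np.sum((A[i] - B[j]) ** 2)) for j in range(9))
            assert got[i] == pytest.approx(expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            min_distance_to_reference(np.zeros((2, 3)), np.zeros((0, 3)))


class TestDistanceTest:
    def test_identical_samples_give_t_zero_p_one(self):
        t, p = subcluster_distance_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_highly_significant(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = subcluster_distance_test(a, a + 100.0)
        assert p < 1e-5

    def test_matches_hand_computed_welch(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        t, p = subcluster_distance_test(a, b)
        # Welch formula by hand
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_constant_equal_samples_convention(self):
        t, p = subcluster_distance_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestSubclusterProfile:
    def test_identical_subclusters_have_zero_difference(self):
        Y = np.tile(np.array([[1.0, 2.0, 3.0]]), (8, 1))
        res = subcluster_expression_profile(Y, [0] * 5 + [1] * 3)
        assert np.allclose(res.mean_difference, 0.0)

    def test_single_shifted_gene(self):
        Y = np.zeros((10, 4))
        assign = np.array([0] * 6 + [1] * 4)
        Y[assign == 1, 2] += 2.0
        res = subcluster_expression_profile(Y, assign)
        # larger cluster (0) minus smaller (1): gene 2 shifted by -2
        assert np.allclose(res.mean_difference, [0, 0, -2.0, 0])
        assert res.sizes == (6, 4)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(62)
        Y = rng.normal(size=(12, 5))
        assign = np.array([0] * 7 + [1] * 5)
        res = subcluster_expression_profile(Y, assign)
        for j in range(5):
            expected = Y[:7, j].mean() - Y[7:, j].mean()
            assert res.mean_difference[j] == pytest.approx(expected)
            assert res.within_sd[j] == pytest.approx(Y[7:, j].std(ddof=1))

    def test_singleton_smaller_cluster_warns(self):
        Y = np.random.default_rng(63).normal(size=(5, 3))
        with pytest.warns(UserWarning, match="singleton"):
            res = subcluster_expression_profile(Y, [0, 0, 0, 0, 1])
        assert np.all(res.within_sd == 0)


class TestProcrustes:
    def test_recovers_similarity_transform_exactly(self):
        rng = np.random.default_rng(64)
        X = rng.normal(size=(20, 2))
        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Xt = 2.5 * X @ R + np.array([3.0, -1.0])
        aligned, err = procrustes_align(Xt, X)
        assert err < 1e-10
        assert np.allclose(aligned, X, atol=1e-9)
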