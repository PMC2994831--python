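"""Within-cluster summaries: spatial mean and GNB discriminant."""

import numpy as np
import pytest

from micmap import (
    ClusterPartition,
    PatternSet,
    fit_gnb,
    gnb_discriminant,
    summarize_mmic,
    summarize_umic,
)


def pattern_set(matrix, labels, runs=None):
    matrix = np.asarray(matrix, dtype=float)
    if runs is None:
        runs = np.arange(matrix.shape[0])
    return PatternSet(matrix, np.asarray(labels), np.asarray(runs))


def two_cluster_partition(sizes=(3, 7)):
    clusters, start = [], 0
    for s in sizes:
        clusters.append(np.arange(start, start + s))
        start += s
    return ClusterPartition(clusters, np.array([], dtype=int), size_threshold=2)


class TestUmic:
    def test_mean_of_three_voxels(self):
        pats = pattern_set([[1, 2, 3]], labels=[0])
        part = ClusterPartition([np.arange(3)], np.array([], dtype=int), 2)
        out = summarize_umic(pats, part)
        assert out.matrix[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(4)
        pats = pattern_set(rng.normal(size=(6, 10)), labels=[0, 1] * 3)
        part = two_cluster_partition()
        out = summarize_umic(pats, part)
        for cid, cluster in enumerate(part.clusters):
            np.testing.assert_allclose(
                out.matrix[:, cid], pats.matrix[:, cluster].mean(axis=1)
            )

    def test_linearity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 10))
        part = two_cluster_partition()
        base = summarize_umic(pattern_set(X, labels=np.arange(5) % 2), part).matrix
        shifted = summarize_umic(
            pattern_set(2.0 * X + 3.0, labels=np.arange(5) % 2), part
        ).matrix
        np.testing.assert_allclose(shifted, 2.0 * base + 3.0, atol=1e-12)


class TestFitGnb:
    def test_hand_computed_parameters(self):
        pats = pattern_set([[0.0], [2.0], [-1.0], [1.0]], labels=[1, 1, 2, 2])
        model = fit_gnb(pats, [0])
        assert model.means[0, 0] == pytest.approx(1.0)   # class 1
        assert model.variances[0, 0] == pytest.approx(1.0)  # ML (biased)
        assert model.means[1, 0] == pytest.approx(0.0)
        assert model.variances[1, 0] == pytest.approx(1.0)
        assert model.log_prior_ratio == pytest.approx(0.0)

    def test_identical_classes_give_identical_parameters(self):
        rng = np.random.default_rng(6)
        block = rng.normal(size=(3, 4))
        pats = pattern_set(np.vstack([block, block]), labels=[0] * 3 + [1] * 3)
        model = fit_gnb(pats, np.arange(4))
        np.testing.assert_allclose(model.means[0], model.means[1])
        np.testing.assert_allclose(model.variances[0], model.variances[1])

    def test_variance_floor_engages_for_constant_responses(self):
        pats = pattern_set([[1.0], [1.0], [0.0], [2.0]], labels=[0, 0, 1, 1])
        model = fit_gnb(pats, [0])
        assert model.variances[0, 0] > 0  # floored, not zero

    def test_too_few_samples_per_class_rejected(self):
        pats = pattern_set([[1.0], [2.0], [3.0]], labels=[0, 0, 1])
        with pytest.raises(ValueError):
            fit_gnb(pats, [0])


class TestGnbDiscriminant:
    def test_symmetric_classes_give_zero(self):
        rng = np.random.default_rng(7)
        block = rng.normal(size=(4, 3))
        pats = pattern_set(np.vstack([block, block]), labels=[0] * 4 + [1] * 4)
        model = fit_gnb(pats, np.arange(3))
        assert gnb_discriminant(model, rng.normal(size=3)) == pytest.approx(0.0)

    def test_midpoint_and_unit_shift(self):
        # mu1=1, mu2=-1, sigma^2=1 both, equal priors
        pats = pattern_set([[0.0], [2.0], [-2.0], [0.0]], labels=[1, 1, 2, 2])
        model = fit_gnb(pats, [0])
        assert gnb_discriminant(model, [0.0]) == pytest.approx(0.0)
        assert gnb_discriminant(model, [1.0]) == pytest.approx(2.0)

    def test_equals_joint_log_density_ratio_oracle(self):
        from scipy.stats import norm

        rng = np.random.default_rng(8)
        for _ in range(20):
            nv = rng.integers(1, 6)
            pats = pattern_set(
                rng.normal(size=(8, nv)), labels=rng.permutation([0] * 4 + [1] * 4)
            )
            model = fit_gnb(pats, np.arange(nv))
            x = rng.normal(size=nv)
            oracle = model.log_prior_ratio + np.log(
                np.prod(norm.pdf(x, model.means[0], np.sqrt(model.variances[0])))
                / np.prod(norm.pdf(x, model.means[1], np.sqrt(model.variances[1])))
            )
            assert gnb_discriminant(model, x) == pytest.approx(oracle, abs=1e-10)


class TestSummarizeMmic:
    def test_test_set_never_influences_fit(self):
        rng = np.random.default_rng(9)
        train = pattern_set(rng.normal(size=(8, 10)), labels=[0, 1] * 4)
        part = two_cluster_partition()
        test_a = pattern_set(rng.normal(size=(4, 10)), labels=[0, 1, 0, 1])
        test_b = pattern_set(rng.normal(size=(4, 10)) * 50, labels=[0, 1, 0, 1])
        tr_a, _ = summarize_mmic(train, test_a, part)
        tr_b, _ = summarize_mmic(train, test_b, part)
        np.testing.assert_array_equal(tr_a.matrix, tr_b.matrix)

    def test_strong_mean_difference_gives_signed_train_discriminants(self):
        rng = np.random.default_rng(10)
        n = 12
        labels = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 10), scale=0.1)
        X[labels == 0, :3] += 5.0  # cluster 0 voxels strongly class-0
        part = two_cluster_partition()
        tr, _ = summarize_mmic(pattern_set(X, labels), pattern_set(X, labels), part)
        # positive discriminant favours the first sorted class (0)
        assert np.all(tr.matrix[labels == 0, 0] > 0)
        assert np.all(tr.matrix[labels == 1, 0] < 0)

    def test_single_voxel_cluster_equals_per_voxel_log_ratio(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 2))
        labels = [0, 1] * 4
        part = ClusterPartition(
            [np.array([0]), np.array([1])], np.array([], dtype=int), 2
        )
        train = pattern_set(X, labels)
        tr, _ = summarize_mmic(train, train, part)
        for v in (0, 1):
            model = fit_gnb(train, [v])
            for s in range(8):
                assert tr.matrix[s, v] == pytest.approx(
                    gnb_discriminant(model, X[s, [v]]), abs=1e-10
                )

    def test_umic_and_mmic_order_samples_identically_under_iid(self):
        """If every voxel shares one distribution per class and class
        variances are equal, the GNB discriminant is monotone in the
        spatial mean, so both summaries sort samples the same way."""
        from micmap import GNBClusterModel

        rng = np.random.default_rng(12)
        n, nv = 10, 6
        labels = np.array([0, 1] * 5)
        X = rng.normal(size=(n, nv)) + np.where(labels == 0, 1.0, -1.0)[:, None]
        part = ClusterPartition([np.arange(nv)], np.array([], dtype=int), 2)
        pats = pattern_set(X, labels)
        u = summarize_umic(pats, part).matrix[:, 0]
        model = GNBClusterModel(
            voxel_indices=np.arange(nv),
            classes=np.array([0, 1]),
            means=np.vstack([np.ones(nv), -np.ones(nv)]),
            variances=np.full((2, nv), 0.8),
            log_prior_ratio=0.0,
        )
        mm = np.array([gnb_discriminant(model, X[s]) for s in range(n)])
        assert np.array_equal(np.argsort(u), np.argsort(mm))
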