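"""Linear SVM training, weight ranking, feature levels and voxel selection."""

import numpy as np
import pytest

from micmap import (
    ClusterPartition,
    WeightMap,
    feature_levels,
    predict,
    rank_features,
    select_voxels,
    train_linear_svm,
    weight_map_from_clusters,
    weight_map_from_voxels,
)


def svm_objective(w, b, X, y, C):
    margins = 1 - y * (X @ w + b)
    return 0.5 * w @ w + C * np.clip(margins, 0, None).sum()


def qp_oracle(X, y, C):
    """Solve the primal soft-margin SVM with explicit slack variables."""
    from scipy.optimize import minimize

    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1:]

    def fun(z):
        w, b, xi = unpack(z)
        return 0.5 * w @ w + C * xi.sum()

    cons = [
        {
            "type": "ineq",
            "fun": lambda z, i=i: unpack(z)[2][i]
            - 1
            + y[i] * (X[i] @ unpack(z)[0] + unpack(z)[1]),
        }
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda z, i=i: unpack(z)[2][i]} for i in range(n)]
    res = minimize(
        fun, np.zeros(d + 1 + n), method="SLSQP", constraints=cons,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return res.fun


class TestTrainLinearSvm:
    def test_one_feature_margin_maximizer(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([-1, 1, -1, 1])
        model = train_linear_svm(X, y, C=1e4)
        assert model.weights[0] == pytest.approx(1.0, abs=1e-3)
        assert model.bias == pytest.approx(0.0, abs=1e-3)

    def test_duplicated_feature_columns_share_weight(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 1))
        y = np.where(X[:, 0] + 0.1 * rng.normal(size=10) > 0, 1, -1)
        Xdup = np.hstack([X, X])
        model = train_linear_svm(Xdup, y, C=1.0)
        assert model.weights[0] == pytest.approx(model.weights[1], abs=1e-8)

    def test_objective_matches_qp_oracle_on_toys(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            X = rng.normal(size=(4, 2))
            y = np.array([1, 1, -1, -1])
            C = 1.0
            model = train_linear_svm(X, y, C=C)
            ours = svm_objective(model.weights, model.bias, X, y, C)
            oracle = qp_oracle(X, y, C)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.ones((4, 2)), np.ones(4))


class TestPredict:
    def test_separable_training_data_classified_perfectly(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(5, 2)) + 4, rng.normal(size=(5, 2)) - 4])
        y = np.array([1] * 5 + [-1] * 5)
        model = train_linear_svm(X, y, C=1e4)
        assert np.array_equal(predict(model, X), y)

    def test_negating_weights_flips_predictions(self):
        from micmap import LinearSVMModel

        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        model = LinearSVMModel(
            weights=np.array([0.5, -1.0, 2.0]), bias=0.3, C=1.0,
            classes=np.array([-1, 1]),
        )
        flipped = LinearSVMModel(
            weights=-model.weights, bias=-model.bias, C=1.0, classes=model.classes
        )
        a, b = predict(model, X), predict(flipped, X)
        assert np.array_equal(a, -b)

    def test_decision_values_match_hand_arithmetic(self):
        from micmap import LinearSVMModel
        from micmap.rank import decision_values

        model = LinearSVMModel(
            weights=np.array([2.0, -1.0]), bias=0.5, C=1.0, classes=np.array([0, 1])
        )
        X = np.array([[1.0, 2.0], [0.0, -1.0]])
        np.testing.assert_allclose(decision_values(model, X), [0.5, 1.5])
        assert list(predict(model, X)) == [1, 1]


class TestRankFeatures:
    def model_with(self, w):
        from micmap import LinearSVMModel

        return LinearSVMModel(
            weights=np.asarray(w, dtype=float), bias=0.0, C=1.0,
            classes=np.array([-1, 1]),
        )

    def test_ranks_by_absolute_weight(self):
        assert list(rank_features(self.model_with([0.5, -2, 1]))) == [1, 2, 0]

    def test_ties_break_by_ascending_index(self):
        assert list(rank_features(self.model_with([1.0, -1.0, 1.0]))) == [0, 1, 2]

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=50)
        order = rank_features(self.model_with(w))
        oracle = sorted(range(50), key=lambda j: (-abs(w[j]), j))
        assert list(order) == oracle


class TestFeatureLevels:
    def test_reference_schedule(self):
        levels = feature_levels()
        assert list(levels[:3]) == [100, 150, 225]
        assert levels[-1] == 3844
        assert len(levels) == 10
        assert np.all(np.diff(levels) > 0)

    def test_exact_powers_of_two(self):
        levels = feature_levels(10, 10 * 2**9, 10)
        assert list(levels) == [10 * 2**k for k in range(10)]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            feature_levels(100, 100, 5)
        with pytest.raises(ValueError):
            feature_levels(10, 20, 1)
        with pytest.raises(ValueError):
            feature_levels(1000, 1001, 10)  # collapses after rounding


class TestSelectVoxels:
    def test_mic_partial_admission(self):
        part = ClusterPartition(
            [np.arange(0, 10), np.arange(10, 20)], np.array([], dtype=int), 10
        )
        w = np.zeros(20)
        w[:10], w[10:] = 2.0, 1.0
        sel = select_voxels(WeightMap(w, "cluster"), part, 15)
        assert len(sel) == 15
        assert set(range(10)) <= set(sel)
        assert list(sel[10:]) == [10, 11, 12, 13, 14]

    def test_full_set_selected_when_n_equals_total(self):
        w = np.array([0.1, 0.9, 0.5])
        sel = select_voxels(WeightMap(w, "voxel"), None, 3)
        assert list(sel) == [0, 1, 2]

    def test_miv_top_n_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        w = rng.uniform(size=40)
        sel = select_voxels(WeightMap(w, "voxel"), None, 12)
        oracle = np.sort(np.argsort(-w)[:12])
        assert np.array_equal(sel, oracle)

    def test_nested_selection_across_levels(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(size=60)
        wm = WeightMap(w, "voxel")
        prev = set()
        for n in (5, 10, 20, 40, 60):
            cur = set(select_voxels(wm, None, n))
            assert prev <= cur
            prev = cur

    def test_mic_nested_selection_and_piecewise_constant_map(self):
        from micmap import LinearSVMModel

        part = ClusterPartition(
            [np.arange(0, 8), np.arange(8, 14), np.arange(14, 20)],
            np.array([20, 21], dtype=int), 6,
        )
        model = LinearSVMModel(
            weights=np.array([0.2, -1.5, 0.7]), bias=0.0, C=1.0,
            classes=np.array([-1, 1]),
        )
        wm = weight_map_from_clusters(model, part, 22)
        for cid, cluster in enumerate(part.clusters):
            assert np.all(wm.values[cluster] == abs(model.weights[cid]))
        assert np.all(wm.values[part.excluded] == 0)
        prev = set()
        for n in (3, 6, 12, 20):
            cur = set(select_voxels(wm, part, n))
            assert prev <= cur and len(cur) == n
            prev = cur

    def test_n_exceeding_available_rejected(self):
        w = np.ones(5)
        with pytest.raises(ValueError):
            select_voxels(WeightMap(w, "voxel"), None, 6)


class TestScaleEquivariance:
    def test_scaling_inputs_preserves_ranking_when_separable(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(size=(6, 4)) + 3, rng.normal(size=(6, 4)) - 3])
        y = np.array([1] * 6 + [-1] * 6)
        m1 = train_linear_svm(X, y, C=1e4)
        m2 = train_linear_svm(5.0 * X, y, C=1e4)
        assert np.array_equal(rank_features(m1), rank_features(m2))
        # w scales as 1/a for a separable problem at large C (solver tolerance)
        np.testing.assert_allclose(m2.weights * 5.0, m1.weights, rtol=1e-2)

    def test_voxel_weight_map_places_weights(self):
        from micmap import LinearSVMModel

        model = LinearSVMModel(
            weights=np.array([1.0, -2.0]), bias=0.0, C=1.0, classes=np.array([0, 1])
        )
        wm = weight_map_from_voxels(model, np.array([3, 7]), 10)
        assert wm.values[3] == 1.0 and wm.values[7] == 2.0
        assert wm.values.sum() == 3.0
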