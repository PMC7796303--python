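"""CART and RPROP-MLP learner behavior."""

import numpy as np
import pytest

from sfqsar import (
    CartModel,
    MlpModel,
    SyntheticSpec,
    fit_cart,
    fit_mlp,
    generate_classification_fixture,
    predict_cart,
    predict_mlp,
    regression_metrics,
)


class TestCart:
    def test_separable_single_split(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(-2, -0.1, 50),
                            rng.uniform(0.1, 2, 50)])[:, None]
        y = (x.ravel() > 0).astype(int)
        model = fit_cart(x, y, ["x"], seed=0)
        pred, _ = predict_cart(model, x, ["x"])
        assert np.array_equal(pred, y)
        assert len(model.nodes) == 3  # one split, two leaves
        assert model.used_descriptors == {"x"}

    def test_used_descriptors_subset(self, separable_task):
        m, labels = separable_task
        model = fit_cart(m.values, labels, m.descriptor_names, seed=1)
        assert model.used_descriptors <= set(m.descriptor_names)

    def test_column_order_invariance(self, separable_task):
        m, labels = separable_task
        model = fit_cart(m.values, labels, m.descriptor_names, seed=2)
        pred1, _ = predict_cart(model, m.values, m.descriptor_names)
        perm = np.arange(m.shape[1])[::-1]
        pred2, _ = predict_cart(model, m.values[:, perm],
                                [m.descriptor_names[j] for j in perm])
        assert np.array_equal(pred1, pred2)

    def test_boundary_goes_left(self):
        model = CartModel(
            feature_names=["x"],
            nodes=[],
        )
        from sfqsar.learners import CartNode
        model.nodes = [
            CartNode(feature="x", threshold=1.0, left=1, right=2,
                     proportions=(0.5, 0.5)),
            CartNode(leaf_class=0, proportions=(1.0, 0.0)),
            CartNode(leaf_class=1, proportions=(0.0, 1.0)),
        ]
        pred, _ = predict_cart(model, np.array([[1.0], [1.0001]]), ["x"])
        assert list(pred) == [0, 1]

    def test_row_permutation_permutes_predictions(self, separable_task):
        m, labels = separable_task
        model = fit_cart(m.values, labels, m.descriptor_names, seed=3)
        pred, _ = predict_cart(model, m.values, m.descriptor_names)
        perm = np.random.default_rng(1).permutation(len(pred))
        pred_perm, _ = predict_cart(model, m.values[perm], m.descriptor_names)
        assert np.array_equal(pred_perm, pred[perm])

    def test_missing_column_raises(self, separable_task):
        m, labels = separable_task
        model = fit_cart(m.values, labels, m.descriptor_names, seed=4)
        if not model.used_descriptors:
            pytest.skip("pruned to root; no descriptor to drop")
        with pytest.raises(ValueError):
            predict_cart(model, m.values[:, :2], ["zz1", "zz2"])

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_cart(np.ones((10, 2)), np.zeros(10, dtype=int), ["a", "b"])

    def test_json_roundtrip(self, separable_task):
        m, labels = separable_task
        model = fit_cart(m.values, labels, m.descriptor_names, seed=5)
        clone = CartModel.from_json(model.to_json())
        assert clone.to_json() == model.to_json()
        p1, _ = predict_cart(model, m.values, m.descriptor_names)
        p2, _ = predict_cart(clone, m.values, m.descriptor_names)
        assert np.array_equal(p1, p2)

    def test_noise_often_collapses_to_root(self):
        """Signal-free labels: internal CV usually prunes everything."""
        roots = 0
        for s in range(20):
            m, labels = generate_classification_fixture(
                SyntheticSpec(n=100, n_descriptors=10, n_informative=1,
                              class_separation=0, seed=500 + s)
            )
            model = fit_cart(m.values, labels, m.descriptor_names, seed=s)
            roots += len(model.nodes) == 1
        assert roots >= 12  # majority collapse; full-rate study in acceptance


class TestMlp:
    def test_constant_target(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 3))
        y = np.full(50, 2.5)
        model = fit_mlp(x, y, ["a", "b", "c"], seed=0)
        pred = predict_mlp(model, x)
        assert np.all(np.abs(pred - 2.5) < 0.05 * 2.5 + 0.01)

    def test_normalization_bounds_exact(self, linear_task):
        m, y = linear_task
        model = fit_mlp(m.values, y, m.descriptor_names, seed=1)
        scaled = (m.values - model.norm_min) / (model.norm_max - model.norm_min)
        np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)

    def test_architecture(self, linear_task):
        m, y = linear_task
        model = fit_mlp(m.values, y, m.descriptor_names, seed=2)
        assert model.layer_sizes == (5, 10, 1)

    def test_forward_pass_matches_hand_oracle(self):
        """Explicit arithmetic on a printed 2-descriptor toy network."""
        w1 = np.array([[0.5, -1.0], [1.0, 0.25]])  # 2 inputs × 2 hidden
        b1 = np.array([0.1, -0.2])
        w2 = np.array([2.0, -0.5])
        b2 = 0.3
        model = MlpModel(
            feature_names=["a", "b"], w1=w1, b1=b1, w2=w2, b2=b2,
            norm_min=np.array([0.0, 0.0]), norm_max=np.array([1.0, 1.0]),
        )
        x = np.array([[0.2, 0.6]])
        z = x @ w1 + b1
        h = 1.0 / (1.0 + np.exp(-z))
        expected = float((h @ w2 + b2)[0])
        assert predict_mlp(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_weights_returns_bias(self):
        model = MlpModel(
            feature_names=["a"], w1=np.zeros((1, 10)), b1=np.zeros(10),
            w2=np.zeros(10), b2=1.25,
            norm_min=np.array([0.0]), norm_max=np.array([1.0]),
        )
        pred = predict_mlp(model, np.array([[0.3], [99.0]]))
        np.testing.assert_allclose(pred, 1.25)

    def test_no_clipping_outside_bounds(self):
        model = MlpModel(
            feature_names=["a"], w1=np.ones((1, 10)), b1=np.zeros(10),
            w2=np.ones(10), b2=0.0,
            norm_min=np.array([0.0]), norm_max=np.array([1.0]),
        )
        inside = predict_mlp(model, np.array([[1.0]]))[0]
        outside = predict_mlp(model, np.array([[5.0]]))[0]
        assert outside > inside  # scaled value 5 passes through unclipped

    def test_deterministic(self, linear_task):
        m, y = linear_task
        m1 = fit_mlp(m.values, y, m.descriptor_names, seed=7)
        m2 = fit_mlp(m.values, y, m.descriptor_names, seed=7)
        assert m1.to_json() == m2.to_json()

    def test_training_reduces_error(self, linear_task):
        m, y = linear_task
        one = fit_mlp(m.values, y, m.descriptor_names, iterations=1, seed=8)
        full = fit_mlp(m.values, y, m.descriptor_names, iterations=100, seed=8)
        rmse1 = regression_metrics(y, predict_mlp(one, m.values))["rmse"]
        rmse100 = regression_metrics(y, predict_mlp(full, m.values))["rmse"]
        assert rmse100 <= rmse1

    def test_local_lipschitz_continuity(self, linear_task):
        m, y = linear_task
        model = fit_mlp(m.values, y, m.descriptor_names, seed=9)
        # bound: |Δout| ≤ ||w2|| · max|w1| / (4·range) · ε  (sigmoid slope ≤ 1/4)
        span = model.norm_max - model.norm_min
        L = np.sum(np.abs(model.w2)[None, :] * np.abs(model.w1) / 4.0
                   / span[:, None], axis=(0, 1))
        x0 = m.values[:5].copy()
        eps = 1e-4
        for j in range(m.shape[1]):
            x1 = x0.copy()
            x1[:, j] += eps
            delta = np.abs(predict_mlp(model, x1) - predict_mlp(model, x0))
            assert np.all(delta <= L * eps + 1e-12)

    def test_constant_descriptor_raises(self):
        x = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError):
            fit_mlp(x, np.arange(20.0), ["const", "ok"])

    def test_rprop_steps_bounded(self, linear_task):
        m, y = linear_task
        # extreme iteration count still cannot push step sizes out of range,
        # observable through finite weights
        model = fit_mlp(m.values, y, m.descriptor_names, iterations=300,
                        seed=10)
        assert np.all(np.isfinite(model.w1)) and np.all(np.isfinite(model.w2))

    def test_json_roundtrip(self, linear_task):
        m, y = linear_task
        model = fit_mlp(m.values, y, m.descriptor_names, seed=11)
        clone = MlpModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            predict_mlp(clone, m.values), predict_mlp(model, m.values)
        )
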