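"""The per-node dense network: forward pass, decision rule, backprop."""

import numpy as np
import pytest

from hdnn import (
    NetworkParams,
    NetworkSpec,
    SyntheticConfig,
    TrainConfig,
    backprop_update,
    decision_rule,
    default_spec,
    forward,
    generate_feature_table,
    init_params,
    train_ann,
)
from hdnn.ann import batch_loss, gradients, predict_ann
from hdnn.errors import DomainError, ShapeError


class TestInit:
    def test_deterministic_per_seed(self):
        spec = NetworkSpec((4, 3, 2))
        a, b = init_params(spec, seed=3), init_params(spec, seed=3)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_reference_topology_shapes(self):
        spec = default_spec(29)
        p = init_params(spec, seed=0)
        assert len(p.weights) == 6
        assert p.weights[0].shape == (512, 29)
        assert p.weights[-1].shape == (2, 16)
        assert all((b == 0).all() for b in p.biases)

    def test_weight_mean_near_zero(self):
        # first layer of a wide net: ~10^5 draws with sd 1/sqrt(fan_in)
        spec = NetworkSpec((100, 1000, 2))
        w = init_params(spec, seed=1).weights[0]
        se = (1 / np.sqrt(100)) / np.sqrt(w.size)
        assert abs(w.mean()) < 3 * se


class TestForward:
    def test_identity_weights_relu_clipping(self):
        spec = NetworkSpec((2, 2, 2))
        p = NetworkParams(weights=[np.eye(2), np.eye(2)], biases=[np.zeros(2), np.zeros(2)])
        tr = forward(p, spec, np.array([1.0, -1.0]))
        np.testing.assert_array_equal(tr.activations[1], [[1.0, 0.0]])
        np.testing.assert_array_equal(tr.scores, [[1.0, 0.0]])

    def test_hand_computed_affine_relu(self):
        # W1=[[1,1],[0,1]], b1=[0,-5], x=[2,3] -> pre [5,-2] -> ReLU [5,0]
        spec = NetworkSpec((2, 2, 2))
        p = NetworkParams(
            weights=[np.array([[1.0, 1.0], [0.0, 1.0]]), np.eye(2)],
            biases=[np.array([0.0, -5.0]), np.zeros(2)],
        )
        tr = forward(p, spec, np.array([2.0, 3.0]))
        np.testing.assert_array_equal(tr.scores, [[5.0, 0.0]])

    def test_all_zero_parameters_give_zero_preactivations(self):
        spec = NetworkSpec((3, 2, 2))
        p = NetworkParams(weights=[np.zeros((2, 3)), np.zeros((2, 2))],
                          biases=[np.zeros(2), np.zeros(2)])
        tr = forward(p, spec, np.array([1.0, 2.0, 3.0]))
        assert all((pre == 0).all() for pre in tr.pre_activations)

    def test_infer_mode_pure_and_train_equals_infer_without_dropout(self):
        spec = NetworkSpec((3, 4, 2), dropout_after=(1,), dropout_rate=0.0)
        p = init_params(spec, seed=2)
        x = np.random.default_rng(0).normal(size=(5, 3))
        a = forward(p, spec, x, mode="infer")
        b = forward(p, spec, x, mode="infer")
        c = forward(p, spec, x, mode="train", seed=123)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.scores, c.scores)

    def test_dropout_only_in_train_mode_with_inverted_scaling(self):
        spec = NetworkSpec((3, 50, 2), dropout_after=(1,), dropout_rate=0.5)
        p = init_params(spec, seed=4)
        x = np.ones((1, 3))
        tr = forward(p, spec, x, mode="train", seed=7)
        mask = tr.dropout_masks[0]
        assert mask is not None
        assert set(np.unique(mask)) <= {0.0, 2.0}  # 1/(1-0.5) scaling
        assert forward(p, spec, x, mode="infer").dropout_masks[0] is None

    def test_shape_and_domain_errors(self):
        spec = NetworkSpec((3, 2, 2))
        p = init_params(spec, seed=0)
        with pytest.raises(ShapeError):
            forward(p, spec, np.ones(4))
        with pytest.raises(DomainError):
            forward(p, spec, np.array([1.0, np.inf, 0.0]))


class TestDecisionRule:
    @pytest.mark.parametrize(
        "scores,expected",
        [([0.2, 0.9], 1), ([0.5, 0.5], 0), ([3.0, 6.0], 1)],
    )
    def test_argmax_with_low_index_ties(self, scores, expected):
        assert decision_rule(np.array(scores)) == expected

    def test_matrix_vector_inner_product_form(self):
        # scores = W x with W=[[1,0],[2,0]], x=[3,1] -> [3,6] -> class 1
        W = np.array([[1.0, 0.0], [2.0, 0.0]])
        x = np.array([3.0, 1.0])
        assert decision_rule(W @ x) == 1

    def test_batch_form_and_empty_error(self):
        out = decision_rule(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_array_equal(out, [0, 1])
        with pytest.raises(DomainError):
            decision_rule(np.array([]))


def _finite_diff(params, spec, X, y, lam, eps=1e-6):
    grads = []
    for w in params.weights + params.biases:
        g = np.zeros_like(w)
        it = np.nditer(w, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            w[i] += eps
            lp = batch_loss(params, spec, X, y, lam=lam)
            w[i] -= 2 * eps
            lm = batch_loss(params, spec, X, y, lam=lam)
            w[i] += eps
            g[i] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads[: len(params.weights)], grads[len(params.weights):]


class TestBackprop:
    @pytest.mark.parametrize("sizes,lam,seed", [
        ((2, 3, 2), 0.0, 0),
        ((3, 4, 3, 2), 0.0, 1),
        ((5, 2, 2), 0.1, 2),
    ])
    def test_gradient_matches_central_finite_differences(self, sizes, lam, seed):
        rng = np.random.default_rng(seed)
        spec = NetworkSpec(sizes)
        params = init_params(spec, seed=seed)
        for b in params.biases:  # keep pre-activations off the ReLU kink
            b += rng.normal(0.0, 0.5, size=b.shape)
        X = rng.normal(size=(6, sizes[0]))
        y = rng.integers(0, 2, 6)
        gw, gb, _ = gradients(params, spec, X, y, lam=lam, train_mode=False)
        nw, nb = _finite_diff(params, spec, X, y, lam)
        for a, n in zip(gw + gb, nw + nb):
            scale = max(np.abs(n).max(), 1e-8)
            assert np.abs(a - n).max() / scale < 1e-5

    def test_regularization_adds_exactly_lambda_w(self):
        rng = np.random.default_rng(3)
        spec = NetworkSpec((3, 3, 2))
        params = init_params(spec, seed=3)
        X = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, 4)
        g0w, g0b, _ = gradients(params, spec, X, y, lam=0.0, train_mode=False)
        g1w, g1b, _ = gradients(params, spec, X, y, lam=0.1, train_mode=False)
        for a, b, w in zip(g1w, g0w, params.weights):
            np.testing.assert_allclose(a - b, 0.1 * w, atol=1e-12)
        for a, b in zip(g1b, g0b):  # biases are never regularized
            np.testing.assert_array_equal(a, b)

    def test_zero_error_batch_leaves_parameters_unchanged(self):
        # Output scores so confident that softmax underflows to exact one-hot:
        # the error signal is identically zero and the step is a no-op.
        spec = NetworkSpec((2, 2, 2))
        params = NetworkParams(
            weights=[np.eye(2) * 1000.0, np.eye(2)],
            biases=[np.zeros(2), np.zeros(2)],
        )
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        new = backprop_update(params, spec, (X, y), TrainConfig(seed=0))
        for a, b in zip(new.weights, params.weights):
            np.testing.assert_array_equal(a, b)


class TestTrainAnn:
    def test_separable_blobs_reach_high_accuracy(self):
        t = generate_feature_table(
            SyntheticConfig(n_positive=250, n_negative=250, n_features=10,
                            effect_size=6.0, n_informative=10, seed=10)
        )
        spec = NetworkSpec((10, 16, 2))
        params, losses = train_ann(t, spec, TrainConfig(epochs=2, learning_rate=0.1, seed=1))
        acc = (predict_ann(params, spec, t.features) == t.labels).mean()
        assert acc >= 0.95
        assert len(losses) == 2

    def test_deterministic_per_config(self, blob_table):
        spec = NetworkSpec((29, 8, 2))
        cfg = TrainConfig(epochs=1, seed=6)
        a, _ = train_ann(blob_table, spec, cfg)
        b, _ = train_ann(blob_table, spec, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_epochs_zero_rejected(self):
        with pytest.raises(DomainError):
            TrainConfig(epochs=0)

    def test_single_class_rejected(self, tiny_table):
        t = tiny_table.take(np.flatnonzero(tiny_table.labels == 1))
        with pytest.raises(DomainError):
            train_ann(t, NetworkSpec((2, 3, 2)), TrainConfig(seed=0))
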