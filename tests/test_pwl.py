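import math
from dataclasses import replace

import numpy as np
import pytest

from msadx.encoding import DesignMatrix, FeatureCodebook, FeatureVar, NormStats
from msadx.pwl import (
    PWLConfig,
    PWLParams,
    PWLPrediction,
    _batch_grad,
    _flat_params,
    forward,
    loss,
    predict_proba,
    train,
)
from msadx.registry import SUBTYPES


def _matrix_from(X, y):
    feats = tuple(FeatureVar(i, f"f{i}", f"f{i}", "O") for i in range(X.shape[1]))
    cb = FeatureCodebook("a", feats)
    labels = np.array([SUBTYPES[i] for i in y], dtype=object)
    return DesignMatrix(np.asarray(X, float), cb, labels, NormStats({}, {}))


@pytest.fixture
def blob_matrix(blobs3):
    X, y = blobs3
    return _matrix_from(X, y)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"label_smoothing": 1.5}, {"l1_ratio": -0.1}, {"reg_coef": -1.0},
        {"dropout_input": 1.0}, {"optimizer": "sgd"},
    ])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            PWLConfig(**kw)


class TestForward:
    def test_untrained_model_is_uniform(self, blob_matrix):
        # head initialised to zero -> zero logits -> p = 1/3 everywhere
        params = train(blob_matrix, PWLConfig(n_epochs=0, n_inner_layers=1,
                                              layer_size=8))
        pred = forward(params, blob_matrix.values)
        np.testing.assert_allclose(pred.probs, 1.0 / 3.0, atol=1e-12)

    def test_probabilities_sum_to_one(self, blob_matrix, tiny_cfg):
        params = train(blob_matrix, tiny_cfg)
        pred = forward(params, blob_matrix.values)
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (pred.probs >= 0).all() and (pred.probs <= 1).all()

    def test_constant_weight_model_equals_direct_matrix_product(self):
        rng = np.random.default_rng(3)
        d, C, n = 5, 3, 40
        X = rng.standard_normal((n, d))
        W0 = rng.standard_normal((C, d)).astype(np.float32)
        b0 = rng.standard_normal(C).astype(np.float32)
        cfg = PWLConfig(constant_weights=True)
        params = PWLParams([], np.concatenate(
            [np.hstack([W0, b0[:, None]]).ravel()]), None, cfg, d,
            [f"f{i}" for i in range(d)])
        pred = forward(params, X)
        oracle = X @ W0.astype(float).T + b0.astype(float)
        np.testing.assert_allclose(pred.logits, oracle, rtol=1e-6)

    def test_weights_exactly_reproduce_logits(self, blob_matrix, tiny_cfg):
        params = train(blob_matrix, tiny_cfg)
        pred = forward(params, blob_matrix.values)
        rebuilt = (pred.weights * blob_matrix.values[:, None, :]).sum(axis=2) \
            + pred.bias
        np.testing.assert_allclose(rebuilt, pred.logits, atol=1e-10)

    def test_dimension_mismatch_raises(self, blob_matrix, tiny_cfg):
        params = train(blob_matrix, tiny_cfg)
        with pytest.raises(ValueError, match="expected"):
            forward(params, np.zeros((4, 7)))


class TestLoss:
    def _pred(self, w, x, probs):
        w = np.asarray(w, float)[:, None, :].repeat(3, axis=1)
        logits = np.log(np.asarray(probs, float))
        return PWLPrediction(w, np.zeros((len(x), 3)), logits,
                             np.asarray(probs, float))

    def test_label_smoothing_targets(self):
        # eps=0.055, C=3: true-class target 0.945 + 0.055/3, off 0.055/3
        eps, C = 0.055, 3
        probs = np.array([[0.7, 0.2, 0.1]])
        pred = self._pred(np.zeros((1, 2)), np.zeros((1, 2)), probs)
        cfg = PWLConfig(label_smoothing=eps, reg_coef=0.0)
        t_true = (1 - eps) + eps / C
        t_off = eps / C
        assert t_true == pytest.approx(0.96333, abs=1e-4)
        expected = -(t_true * math.log(0.7) + t_off * math.log(0.2)
                     + t_off * math.log(0.1))
        assert loss(pred, np.array([0]), cfg) == pytest.approx(expected)

    def test_no_smoothing_no_penalty_is_plain_cross_entropy(self):
        probs = np.array([[0.5, 0.25, 0.25], [0.1, 0.8, 0.1]])
        pred = self._pred(np.zeros((2, 2)), np.zeros((2, 2)), probs)
        cfg = PWLConfig(label_smoothing=0.0, reg_coef=0.0)
        expected = -(math.log(0.5) + math.log(0.8)) / 2
        assert loss(pred, np.array([0, 1]), cfg) == pytest.approx(expected)

    def test_two_sample_toy_with_penalty_matches_hand_arithmetic(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]])
        w = np.array([[1.0, -2.0], [0.5, 0.0]])  # per-sample weights
        pred = self._pred(w, np.zeros((2, 2)), probs)
        lam, alpha, eps = 0.1, 0.5, 0.0
        cfg = PWLConfig(label_smoothing=eps, reg_coef=lam, l1_ratio=alpha)
        ce = -(math.log(0.6) + math.log(0.5)) / 2
        # each weight row is repeated over the 3 classes by _pred
        l1 = (3 * (1 + 2) + 3 * 0.5) / 2
        l2 = (3 * (1 + 4) + 3 * 0.25) / 2
        expected = ce + lam * (alpha * l1 + (1 - alpha) * 0.5 * l2)
        assert loss(pred, np.array([0, 1]), cfg) == pytest.approx(expected)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 4)).astype(np.float32)
        y = rng.integers(0, 3, 12)
        cfg = PWLConfig(n_epochs=0, n_inner_layers=2, layer_size=6,
                        dropout_inner=0.0, dropout_input=0.0,
                        reg_coef=1e-3, l1_ratio=0.0, seed=1)
        params = train(_matrix_from(X, y), cfg)
        # nudge the head away from zero so trunk gradients are non-trivial
        params.W_head += rng.standard_normal(params.W_head.shape).astype(
            np.float32) * 0.05
        _, grads = _batch_grad(params, X, y, rng)
        flat = _flat_params(params)
        for pi in [0, 3, len(flat) - 2, len(flat) - 1]:
            p, g = flat[pi], grads[pi]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            h = 1e-2
            orig = p[idx]
            p[idx] = orig + h
            lp, _ = _batch_grad(params, X, y, rng)
            p[idx] = orig - h
            lm, _ = _batch_grad(params, X, y, rng)
            p[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=5e-2, abs=5e-4)


class TestTraining:
    def test_same_seed_same_parameters(self, blob_matrix, tiny_cfg):
        p1 = train(blob_matrix, tiny_cfg)
        p2 = train(blob_matrix, tiny_cfg)
        for a, b in zip(_flat_params(p1), _flat_params(p2)):
            np.testing.assert_array_equal(a, b)
        assert p1.history == p2.history

    def test_single_class_training_set_rejected(self, blobs3, tiny_cfg):
        X, y = blobs3
        m = _matrix_from(X, np.zeros_like(y))
        with pytest.raises(ValueError, match="single class"):
            train(m, tiny_cfg)

    def test_separable_blobs_reach_near_perfect_auc(self, blob_matrix):
        from sklearn.linear_model import LogisticRegression

        from msadx.evaluation import ovr_mean_auc

        cfg = PWLConfig(n_epochs=100, n_inner_layers=2, layer_size=32,
                        learning_rate=3e-3, batch_size=64, seed=0)
        params = train(blob_matrix, cfg)
        pred = forward(params, blob_matrix.values)
        _, auc = ovr_mean_auc(pred.probs, blob_matrix.y)
        assert auc > 0.99
        # independent oracle: plain logistic regression separates this data
        lr = LogisticRegression(max_iter=1000).fit(blob_matrix.values,
                                                   blob_matrix.y)
        _, auc_lr = ovr_mean_auc(lr.predict_proba(blob_matrix.values),
                                 blob_matrix.y)
        assert auc_lr == pytest.approx(1.0, abs=1e-9)

    def test_training_loss_decreases(self, blob_matrix, tiny_cfg):
        params = train(blob_matrix, tiny_cfg)
        assert params.history[-1] < params.history[0]

    def test_strong_penalty_shrinks_emitted_weights(self, blob_matrix):
        base = dict(n_epochs=30, n_inner_layers=2, layer_size=16,
                    learning_rate=3e-3, seed=0)
        free = train(blob_matrix, PWLConfig(reg_coef=0.0, **base))
        tight = train(blob_matrix, PWLConfig(reg_coef=10.0, **base))
        l1 = lambda p: np.abs(forward(p, blob_matrix.values).weights).sum(
            axis=(1, 2)).mean()
        assert l1(tight) < l1(free)

    def test_penalty_monotonicity_over_lambda_grid(self, blob_matrix):
        base = dict(n_epochs=30, n_inner_layers=2, layer_size=16,
                    learning_rate=3e-3, seed=0)
        norms = []
        for lam in (0.0, 1e-4, 1e-2, 1.0):
            p = train(blob_matrix, PWLConfig(reg_coef=lam, **base))
            w = forward(p, blob_matrix.values).weights
            norms.append(np.abs(w).sum(axis=(1, 2)).mean())
        for a, b in zip(norms, norms[1:]):
            assert b <= a * 1.05  # non-increasing up to 5% optimisation noise


class TestReducedModes:
    def test_constant_weight_mode_matches_logistic_regression(self, blobs3):
        from sklearn.linear_model import LogisticRegression

        from msadx.evaluation import ovr_mean_auc

        rng = np.random.default_rng(5)
        X, y = blobs3
        X = X + rng.standard_normal(X.shape) * 1.5  # make it imperfect
        m = _matrix_from(X, y)
        cfg = PWLConfig(constant_weights=True, n_epochs=300,
                        learning_rate=0.05, label_smoothing=0.0,
                        reg_coef=0.0, dropout_input=0.0, seed=0)
        params = train(m, cfg)
        _, auc = ovr_mean_auc(forward(params, X).probs, y)
        lr = LogisticRegression(max_iter=2000, C=1e6).fit(X, y)
        _, auc_lr = ovr_mean_auc(lr.predict_proba(X), y)
        assert auc == pytest.approx(auc_lr, abs=0.02)

    def test_one_vs_rest_mode(self, blob_matrix):
        from msadx.evaluation import ovr_mean_auc

        cfg = PWLConfig(n_epochs=40, n_inner_layers=2, layer_size=16,
                        learning_rate=3e-3, ovr_models=True, seed=0)
        params = train(blob_matrix, cfg)
        pred = forward(params, blob_matrix.values)
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-9)
        _, auc = ovr_mean_auc(pred.probs, blob_matrix.y)
        assert auc > 0.95


class TestPredictProba:
    def test_table_shape_and_argmax_flag(self, blob_matrix, tiny_cfg):
        params = train(blob_matrix, tiny_cfg)
        table = predict_proba(params, blob_matrix)
        assert list(table.columns) == ["SND", "SDS", "OPCA", "predicted"]
        np.testing.assert_allclose(
            table[["SND", "SDS", "OPCA"]].sum(axis=1), 1.0, atol=1e-9)
        i = table[["SND", "SDS", "OPCA"]].to_numpy().argmax(axis=1)
        assert (table["predicted"] == np.array(SUBTYPES)[i]).all()
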