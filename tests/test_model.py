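"""Model-layer tests: shape contracts, hand oracles, gradient checks."""

import numpy as np
import pytest

from cnndlp import _nn
from cnndlp.model import (
    DualModel,
    ModelConfig,
    PairScore,
    classification_loss,
    conv_pool_block,
    fuse_scores,
    reconstruction_loss,
)


def numgrad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestConvPoolBlock:
    @pytest.mark.parametrize("nl,nd,nm", [(5, 4, 3), (10, 7, 2), (60, 40, 50), (3, 3, 3), (17, 9, 30)])
    def test_first_conv_shape_contract(self, rng, nl, nd, nm):
        # padded 2-row embedding -> (4-w+1) x (2+N-h+1) feature maps
        n = nl + nd + nm
        x = rng.random((2, n))
        filters = rng.normal(size=(16, 1, 2, 2))
        z, _ = conv_pool_block(x, filters, np.zeros(16))
        assert z.shape == (1, 16, 3, n + 1)

    def test_all_negative_preactivations_zero_output(self):
        x = np.ones((2, 5))
        filters = -np.ones((1, 1, 2, 2))
        z, v = conv_pool_block(x, filters, np.zeros(1))
        assert (z == 0).all() and (v == 0).all()

    def test_identity_filter_shifts_input(self, rng):
        # filter [[1,0],[0,0]] with zero bias copies the padded frame
        x = rng.random((2, 3))
        filters = np.zeros((1, 1, 2, 2))
        filters[0, 0, 0, 0] = 1.0
        z, _ = conv_pool_block(x, filters, np.zeros(1))
        padded = np.pad(x, 1)
        np.testing.assert_allclose(z[0, 0], np.maximum(padded[:3, :4], 0))

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            conv_pool_block(np.ones((2, 5)), np.ones((1, 1, 6, 6)), np.zeros(1))


class TestPoolUnpool:
    def test_unpool_restores_argmax_positions(self, rng):
        x = rng.normal(size=(1, 1, 4, 4))
        pool = _nn.MaxPool()
        v = pool.forward(x, train=False)
        r = _nn.MaxUnpool(pool).forward(v, train=False)
        for wi in range(2):
            for wj in range(2):
                win = x[0, 0, 2 * wi : 2 * wi + 2, 2 * wj : 2 * wj + 2]
                sub = r[0, 0, 2 * wi : 2 * wi + 2, 2 * wj : 2 * wj + 2]
                expect = np.zeros((2, 2))
                expect[np.unravel_index(win.argmax(), (2, 2))] = win.max()
                np.testing.assert_allclose(sub, expect)

    def test_ceil_mode_round_trip_shape(self, rng):
        x = rng.normal(size=(2, 3, 3, 9))
        pool = _nn.MaxPool()
        v = pool.forward(x, train=False)
        assert v.shape == (2, 3, 2, 5)
        assert _nn.MaxUnpool(pool).forward(v, train=False).shape == x.shape


class TestLeftBranch:
    def test_softmax_outputs_sum_to_one(self, rng):
        m = DualModel(23, ModelConfig(seed=1))
        X = rng.random((4, 2, 23))
        logits = m.left.forward(X, train=False)
        p = _nn.softmax(logits, axis=-1)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-9)

    def test_deterministic_inference(self, rng):
        m = DualModel(23, ModelConfig(seed=1))
        X = rng.random((4, 2, 23))
        a, _, _ = m.score(X, X)
        b, _, _ = m.score(X, X)
        np.testing.assert_array_equal(a, b)

    def test_zero_weight_head_gives_half(self, rng):
        m = DualModel(23, ModelConfig(seed=1))
        m.left.dense.W[...] = 0.0
        m.left.dense.b[...] = 0.0
        X = rng.random((3, 2, 23))
        sl, _, _ = m.score(X, X)
        np.testing.assert_allclose(sl, 0.5, atol=1e-12)


class TestAutoencoder:
    def test_decoder_restores_input_shape(self, rng):
        for n in (11, 24, 37):
            m = DualModel(n, ModelConfig(seed=2))
            Y = rng.random((3, 2, n))
            _, y_rec, _ = m.right.forward(Y, train=False)
            assert y_rec.shape == Y.shape

    def test_code_is_spatially_low_dimensional(self, rng):
        n = 40
        m = DualModel(n, ModelConfig(seed=2))
        _, _, code = m.right.forward(rng.random((2, 2, n)), train=False)
        spatial = code.shape[2] * code.shape[3]
        assert spatial < 2 * n

    def test_training_decreases_combined_loss(self, rng):
        # fixed seeded batch: loss2 + loss_auto decreases over first 20 epochs
        n = 30
        m = DualModel(n, ModelConfig(seed=3))
        Y = rng.random((16, 2, n))
        labels = (rng.random(16) < 0.5).astype(int)
        losses = []
        for _ in range(20):
            logits, y_rec, _ = m.right.forward(Y, train=True)
            p1, ce, grad = _nn.softmax_xent(logits, labels)
            losses.append(ce + reconstruction_loss(Y, y_rec))
            g_rec = 2.0 * (y_rec - Y) / len(Y)
            m.right.backward(grad, g_rec)
            m.opt_right.step()
        increases = sum(b >= a for a, b in zip(losses, losses[1:]))
        assert increases <= 2
        assert losses[-1] < losses[0]


class TestLosses:
    def test_reconstruction_zero_at_identity(self, rng):
        y = rng.random((3, 2, 5))
        assert reconstruction_loss(y, y) == 0.0

    def test_reconstruction_single_sample_value(self):
        assert reconstruction_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])) == 1.0

    def test_reconstruction_quadratic_scaling(self, rng):
        y = rng.random((2, 2, 4))
        r = rng.random((2, 2, 4))
        base = reconstruction_loss(y, y + r)
        assert reconstruction_loss(y, y + 3 * r) == pytest.approx(9 * base)

    def test_classification_closed_forms(self):
        assert classification_loss([0.5], [1]) == pytest.approx(np.log(2))
        assert classification_loss([0.5], [0]) == pytest.approx(np.log(2))
        assert classification_loss([1.0 - 1e-15], [1]) == pytest.approx(0.0, abs=1e-9)

    def test_classification_clamped_at_extremes(self):
        assert np.isfinite(classification_loss([0.0], [1]))
        assert np.isfinite(classification_loss([1.0], [0]))

    def test_classification_gradient_matches_finite_difference(self):
        s = np.array([0.3])
        y = np.array([1.0])
        analytic = -(y / s - (1 - y) / (1 - s))
        num = numgrad(lambda: classification_loss(s, y), s)
        np.testing.assert_allclose(num, analytic, atol=1e-5)

    def test_fuse_scores_endpoints_and_value(self):
        assert fuse_scores(0.8, 0.6, 1.0) == 0.8
        assert fuse_scores(0.8, 0.6, 0.0) == 0.6
        assert fuse_scores(0.8, 0.6, 0.3) == pytest.approx(0.66)

    def test_fuse_scores_bad_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            fuse_scores(0.5, 0.5, -0.1)

    def test_pair_score_contract(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PairScore(score_left=1.2, score_right=0.5, score=0.5, label=1)


class TestGradients:
    """Every layer's backward pass against central finite differences."""

    def _check(self, layer, x, rng, tol=1e-5):
        w = rng.normal(size=layer.forward(x, True).shape)

        def loss():
            return float((layer.forward(x, True) * w).sum())

        loss()
        gx = layer.backward(w.copy())
        assert np.abs(gx - numgrad(loss, x)).max() < tol
        for p, g in zip(layer.params, layer.grads):
            loss()
            layer.backward(w.copy())
            assert np.abs(g - numgrad(loss, p)).max() < tol

    def test_conv(self, rng):
        self._check(_nn.Conv(2, 3, (2, 2), rng), rng.normal(size=(3, 2, 4, 7)), rng)

    def test_transpose_conv(self, rng):
        self._check(_nn.TransposeConv(2, 3, (2, 2), rng), rng.normal(size=(3, 2, 4, 7)), rng)

    def test_batchnorm(self, rng):
        self._check(_nn.BatchNorm(2), rng.normal(size=(4, 2, 3, 5)), rng)

    def test_dense(self, rng):
        self._check(_nn.Dense(6, 3, rng), rng.normal(size=(5, 6)), rng)

    def test_attention(self, rng):
        self._check(_nn.Attention(4, rng), rng.normal(size=(3, 2, 8)), rng)

    def test_pool_and_unpool(self, rng):
        pool = _nn.MaxPool()
        x = rng.normal(size=(2, 2, 3, 7))
        self._check(pool, x, rng)
        v = pool.forward(x, True)
        self._check(_nn.MaxUnpool(pool), v, rng)


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        m = DualModel(19, ModelConfig(seed=4))
        X = rng.random((6, 2, 19))
        Y = rng.random((6, 2, 19))
        labels = np.array([0, 1, 0, 1, 1, 0])
        m.fit_config = None
        m.config = ModelConfig(seed=4, epochs=2)
        m.fit(X, Y, labels)
        m.save(tmp_path / "ckpt")
        m2 = DualModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(m.score(X, Y)[2], m2.score(X, Y)[2])
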