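"""Finite-difference verification of the numpy network engine.

Every layer's backward pass is checked against central differences on
small float64 instances; the trainer is checked for reproducibility and
loss descent.
"""

import numpy as np
import pytest

from donorscreen import nncore
from donorscreen.nncore import (
    Adam, BatchNorm, Dense, Dropout, LeakyReLU, Network, ReLU, Reshape,
    ResBlock, TemporalConv, ZeroUpsample, fit_network, mse_loss,
    weighted_bce_loss,
)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def check_layer_grads(layer, x, training=True, atol=1e-6):
    """Compare analytic input and parameter grads with central differences
    under the scalar loss L = sum(forward(x)^2) / 2."""
    def loss():
        y = layer.forward(x, training=training)
        return 0.5 * float((y**2).sum())

    y = layer.forward(x, training=training)
    dx = layer.backward(y)

    dx_num = numeric_grad(loss, x)
    np.testing.assert_allclose(dx, dx_num, atol=atol, rtol=1e-4)
    for p, g in zip(layer.params, layer.grads):
        layer.forward(x, training=training)
        layer.backward(layer.forward(x, training=training))
        g_num = numeric_grad(loss, p)
        np.testing.assert_allclose(g, g_num, atol=atol, rtol=1e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestLayerGradients:
    def test_dense(self, rng):
        lay = Dense(4, 3, rng, dtype=np.float64)
        check_layer_grads(lay, rng.standard_normal((5, 4)))

    @pytest.mark.parametrize("stride,pad", [(1, None), (2, None), (1, 0)])
    def test_temporal_conv(self, rng, stride, pad):
        lay = TemporalConv(2, 3, 3, rng, stride=stride, pad=pad,
                           dtype=np.float64)
        check_layer_grads(lay, rng.standard_normal((4, 9, 2)))

    def test_resblock_with_projection(self, rng):
        lay = ResBlock(2, 4, 3, rng, stride=2, alpha=0.1, batchnorm=True,
                       dtype=np.float64)
        check_layer_grads(lay, rng.standard_normal((3, 9, 2)))

    def test_resblock_identity_shortcut(self, rng):
        lay = ResBlock(3, 3, 3, rng, stride=1, dtype=np.float64)
        check_layer_grads(lay, rng.standard_normal((3, 7, 3)))

    def test_batchnorm_training_mode(self, rng):
        lay = BatchNorm(3, dtype=np.float64)
        check_layer_grads(lay, rng.standard_normal((6, 5, 3)), atol=1e-5)

    def test_zero_upsample_roundtrip(self, rng):
        lay = ZeroUpsample(2)
        x = rng.standard_normal((2, 5, 3))
        y = lay.forward(x)
        assert y.shape == (2, 9, 3)
        np.testing.assert_array_equal(lay.backward(y), x)

    def test_activations(self, rng):
        x = rng.standard_normal((4, 4))
        for lay in (ReLU(), LeakyReLU(0.1)):
            check_layer_grads(lay, x.copy())


class TestLosses:
    def test_mse_grad(self, rng):
        pred = rng.standard_normal((5, 3))
        tgt = rng.standard_normal((5, 3))
        loss, grad = mse_loss(pred, tgt)
        g_num = numeric_grad(
            lambda: mse_loss(pred, tgt)[0], pred
        )
        np.testing.assert_allclose(grad, g_num, atol=1e-6)

    def test_weighted_bce_matches_manual(self, rng):
        logits = rng.standard_normal((6, 1))
        y = np.array([1, 0, 1, 0, 0, 1], float)
        w = np.array([5.0, 1, 5, 1, 1, 5])
        loss, grad = weighted_bce_loss(logits, y, w)
        p = 1 / (1 + np.exp(-logits.ravel()))
        manual = -(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / w.sum()
        assert loss == pytest.approx(manual, rel=1e-5)
        g_num = numeric_grad(lambda: weighted_bce_loss(logits, y, w)[0],
                             logits)
        np.testing.assert_allclose(grad, g_num, atol=1e-6)


class TestTrainer:
    def _toy(self, rng):
        X = rng.standard_normal((64, 5)).astype(np.float32)
        w_true = rng.standard_normal((5, 1))
        y = (X @ w_true + 0.1 * rng.standard_normal((64, 1))).astype(
            np.float32
        )
        return X, y

    def _net(self, seed):
        rng = np.random.default_rng(seed)
        return Network([Dense(5, 8, rng), ReLU(), Dense(8, 1, rng)])

    def test_loss_decreases(self, rng):
        X, y = self._toy(rng)
        net = self._net(1)
        hist = fit_network(net, X, y, loss_fn=mse_loss, epochs=30,
                           batch_size=16, rng=np.random.default_rng(2))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_bit_reproducible(self, rng):
        X, y = self._toy(rng)
        outs = []
        for _ in range(2):
            net = self._net(3)
            fit_network(net, X, y, loss_fn=mse_loss, epochs=5,
                        batch_size=16, rng=np.random.default_rng(4))
            outs.append(net.forward(X))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_early_stopping_restores_best(self, rng):
        X, y = self._toy(rng)
        net = self._net(5)
        hist = fit_network(net, X, y, loss_fn=mse_loss, X_val=X[:16],
                           y_val=y[:16], epochs=40, batch_size=16,
                           patience=3, rng=np.random.default_rng(6))
        # restored weights reproduce the best validation loss
        final_val = mse_loss(net.forward(X[:16]), y[:16])[0]
        assert final_val == pytest.approx(min(hist["val_loss"]), rel=1e-5)

    def test_l2_shrinks_weights(self, rng):
        X, y = self._toy(rng)
        net_a, net_b = self._net(7), self._net(7)
        fit_network(net_a, X, y, loss_fn=mse_loss, epochs=20, batch_size=16,
                    l2=0.0, rng=np.random.default_rng(8))
        fit_network(net_b, X, y, loss_fn=mse_loss, epochs=20, batch_size=16,
                    l2=0.1, rng=np.random.default_rng(8))
        norm = lambda net: sum(float((p**2).sum())
                               for p, _, d in net.parameters() if d)
        assert norm(net_b) < norm(net_a)

    def test_dropout_off_at_inference(self, rng):
        drop = Dropout(0.5, np.random.default_rng(9))
        x = rng.standard_normal((10, 10))
        np.testing.assert_array_equal(drop.forward(x, training=False), x)
        y = drop.forward(x, training=True)
        assert (y == 0).sum() > 0


def test_batchnorm_running_stats_persist():
    rng = np.random.default_rng(10)
    net = Network([BatchNorm(3)])
    x = rng.standard_normal((50, 3)).astype(np.float32) * 4 + 1
    for _ in range(20):
        net.forward(x, training=True)
    w = net.get_weights()
    net2 = Network([BatchNorm(3)])
    net2.set_weights(w)
    np.testing.assert_allclose(net2.forward(x, training=False),
                               net.forward(x, training=False))
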