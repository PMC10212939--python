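"""A compact numpy neural-network engine for the screening models.

Provides exactly what the temporal autoencoder and classifier need and
nothing more: dense layers, temporal 1-D convolutions that slide only
along the time-block axis (shared across analytes), zero-insertion
upsampling for the mirrored decoder, ReLU, inverted dropout, residual
blocks, Adam with decoupled-from-bias L2, mean-squared-error and weighted
binary cross-entropy losses, and a mini-batch trainer with early stopping
and best-weight restoration.

All randomness (initialisation, dropout, shuffling) flows through numpy
Generators supplied by the caller, so training is bit-reproducible on one
device.  Gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "TemporalConv", "ZeroUpsample", "ReLU", "Dropout", "Reshape",
    "ResBlock", "Network", "Adam", "mse_loss", "weighted_bce_loss",
    "fit_network", "sigmoid",
]


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    params: list
    grads: list
    decay: list  # parallel flags: apply L2 to this param?
    state: list  # non-trainable arrays that must persist (e.g. BN stats)

    def __init__(self):
        self.params, self.grads, self.decay, self.state = [], [], [], []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.b = np.zeros(n_out, dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class TemporalConv(Layer):
    """1-D convolution on (batch, length, channels) with 'same' padding for
    stride 1 and symmetric padding ``pad`` otherwise."""

    def __init__(self, c_in, c_out, k, rng, stride=1, pad=None, dtype=np.float32):
        super().__init__()
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = (rng.standard_normal((k * c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]
        self.c_in, self.c_out = c_in, c_out

    def _cols(self, xp, l_out):
        # (B, l_out, k, C) view, stride applied along length
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        win = win[:, :: self.stride][:, :l_out]  # (B, l_out, C, k)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2))

    def forward(self, x, training=False):
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        l_out = (L + 2 * self.pad - self.k) // self.stride + 1
        cols = self._cols(xp, l_out)
        self._cols_cache, self._in_shape = cols, x.shape
        y = cols.reshape(B * l_out, self.k * C) @ self.W + self.b
        return y.reshape(B, l_out, self.c_out)

    def backward(self, dy):
        B, L, C = self._in_shape
        l_out = dy.shape[1]
        dyf = dy.reshape(B * l_out, self.c_out)
        colsf = self._cols_cache.reshape(B * l_out, self.k * C)
        self.grads[0][...] = colsf.T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(B, l_out, self.k, C)
        dxp = np.zeros((B, L + 2 * self.pad, C), dtype=dy.dtype)
        # window positions are distinct for fixed kernel offset -> slice add
        for ki in range(self.k):
            end = ki + self.stride * (l_out - 1) + 1
            dxp[:, ki : end : self.stride] += dcols[:, :, ki]
        return dxp[:, self.pad : self.pad + L]


class ZeroUpsample(Layer):
    """Insert stride-1 zeros between time steps: L -> (L-1)*s + 1."""

    def __init__(self, stride=2):
        super().__init__()
        self.stride = stride

    def forward(self, x, training=False):
        B, L, C = x.shape
        out = np.zeros((B, (L - 1) * self.stride + 1, C), dtype=x.dtype)
        out[:, :: self.stride] = x
        return out

    def backward(self, dy):
        return dy[:, :: self.stride]


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (feature/channel).

    Works for both (B, F) dense activations and (B, L, C) temporal maps.
    Running statistics (momentum 0.9) serve inference.
    """

    def __init__(self, n_features, dtype=np.float32, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(n_features, dtype)
        self.beta = np.zeros(n_features, dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.decay = [False, False]
        self.run_mean = np.zeros(n_features, dtype)
        self.run_var = np.ones(n_features, dtype)
        self.state = [self.run_mean, self.run_var]
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean[...] = m * self.run_mean + (1 - m) * mu
            self.run_var[...] = m * self.run_var + (1 - m) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = (x - mu) * self._inv
        self._axes, self._n = axes, int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = self._axes
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma * self._inv
        n = self._n
        t = dy - dy.mean(axis=axes) - self._xhat * (
            (dy * self._xhat).sum(axis=axes) / n
        )
        return t * self.gamma * self._inv


class ReLU(Layer):
    def forward(self, x, training=False):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class LeakyReLU(Layer):
    """max(x, alpha*x); avoids dead units in the narrow AE bottleneck."""

    def __init__(self, alpha=0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._m = x > 0
        return np.where(self._m, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._m, dy, self.alpha * dy)


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Reshape(Layer):
    """Pure view change; ``shape_fn(in_shape) -> out_shape``."""

    def __init__(self, shape_fn):
        super().__init__()
        self.shape_fn = shape_fn

    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(self.shape_fn(x.shape))

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class ResBlock(Layer):
    """conv -> (+ shortcut) -> (leaky) relu; 1x1 projection when shape
    changes."""

    def __init__(self, c_in, c_out, k, rng, stride=1, alpha=0.0,
                 batchnorm=False, dtype=np.float32):
        super().__init__()
        self.alpha = alpha
        self.conv = TemporalConv(c_in, c_out, k, rng, stride=stride, dtype=dtype)
        self.bn = BatchNorm(c_out, dtype) if batchnorm else None
        self.proj = None
        self.bn_proj = None
        if c_in != c_out or stride != 1:
            self.proj = TemporalConv(c_in, c_out, 1, rng, stride=stride, pad=0,
                                     dtype=dtype)
            if batchnorm:
                self.bn_proj = BatchNorm(c_out, dtype)
        for p in (self.conv, self.bn, self.proj, self.bn_proj):
            if p is not None:
                self.params += p.params
                self.grads += p.grads
                self.decay += p.decay
                self.state += p.state

    def forward(self, x, training=False):
        y = self.conv.forward(x, training)
        if self.bn:
            y = self.bn.forward(y, training)
        s = self.proj.forward(x, training) if self.proj else x
        if self.bn_proj:
            s = self.bn_proj.forward(s, training)
        act = y + s
        self._m = act > 0
        if self.alpha:
            return np.where(self._m, act, self.alpha * act)
        return act * self._m

    def backward(self, dy):
        if self.alpha:
            dy = np.where(self._m, dy, self.alpha * dy)
        else:
            dy = dy * self._m
        db = self.bn.backward(dy) if self.bn else dy
        dx = self.conv.backward(db)
        if self.proj:
            ds = self.bn_proj.backward(dy) if self.bn_proj else dy
            dx = dx + self.proj.backward(ds)
        else:
            dx = dx + dy
        return dx


class Network:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def parameters(self):
        out = []
        for lay in self.layers:
            out += list(zip(lay.params, lay.grads, lay.decay))
        return out

    def get_weights(self):
        return [p.copy() for lay in self.layers for p in lay.params + lay.state]

    def set_weights(self, weights):
        flat = [p for lay in self.layers for p in lay.params + lay.state]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


class Adam:
    def __init__(self, net: Network, lr=1e-3, l2=0.0, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.net, self.lr, self.l2 = net, lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in net.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, decay) in enumerate(self.net.parameters()):
            grad = g + (2.0 * self.l2 * p if (decay and self.l2) else 0.0)
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def mse_loss(pred, target):
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 * diff / diff.size).astype(pred.dtype)


def weighted_bce_loss(logits, y, w=None):
    """Weighted binary cross-entropy on logits; grad wrt logits."""
    y = y.reshape(logits.shape).astype(logits.dtype)
    if w is None:
        w = np.ones_like(y)
    else:
        w = w.reshape(logits.shape).astype(logits.dtype)
    p = sigmoid(logits)
    eps = 1e-12
    ce = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    wsum = float(w.sum())
    loss = float((w * ce).sum() / wsum)
    grad = (w * (p - y) / wsum).astype(logits.dtype)
    return loss, grad


def _epoch_loss(net, X, y, loss_fn, w=None, batch=4096):
    total, n = 0.0, 0
    for s in range(0, len(X), batch):
        xb = X[s : s + batch]
        out = net.forward(xb, training=False)
        if w is None:
            l, _ = loss_fn(out, y[s : s + batch])
        else:
            l, _ = loss_fn(out, y[s : s + batch], w[s : s + batch])
        total += l * len(xb)
        n += len(xb)
    return total / max(n, 1)


def fit_network(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    *,
    loss_fn=mse_loss,
    sample_weight: np.ndarray | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    val_weight: np.ndarray | None = None,
    epochs: int = 100,
    batch_size: int = 256,
    lr: float = 1e-3,
    l2: float = 0.0,
    patience: int | None = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mini-batch Adam training with optional early stopping.

    When a validation set and patience are given, the best-validation-loss
    weights are restored at the end and ``history['best_epoch']`` records
    the selected epoch (1-based count of epochs actually useful).
    """
    rng = rng or np.random.default_rng(0)
    opt = Adam(net, lr=lr, l2=l2)
    history = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val, best_w, since_best = np.inf, None, 0
    monitor = X_val is not None and patience is not None

    for epoch in range(epochs):
        order = rng.permutation(len(X))
        run, seen = 0.0, 0
        for s in range(0, len(X), batch_size):
            b = order[s : s + batch_size]
            out = net.forward(X[b], training=True)
            if sample_weight is None:
                l, g = loss_fn(out, y[b])
            else:
                l, g = loss_fn(out, y[b], sample_weight[b])
            net.backward(g)
            opt.step()
            run += l * len(b)
            seen += len(b)
        history["train_loss"].append(run / seen)
        if X_val is not None:
            vl = _epoch_loss(net, X_val, y_val, loss_fn, val_weight)
            history["val_loss"].append(vl)
            if vl < best_val - 1e-9:
                best_val, best_w, since_best = vl, net.get_weights(), 0
                history["best_epoch"] = epoch + 1
            else:
                since_best += 1
                if monitor and since_best >= patience:
                    break
    if monitor and best_w is not None:
        net.set_weights(best_w)
    if history["best_epoch"] is None:
        history["best_epoch"] = len(history["train_loss"])
    return history
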