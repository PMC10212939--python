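"""The three screening models with a uniform train/predict contract.

* :class:`TemporalAutoencoder` — a ResNet-style convolutional autoencoder
  whose kernels slide only along the 9-block time axis (extent 1 on the
  analyte axis, weights shared across analytes).  Trained by
  reconstruction on non-donor patients only, it embeds each patient's
  analyte x block grid into a low-dimensional latent vector and doubles as
  an anomaly detector through its reconstruction error.
* :class:`DeepClassifier` — four fully connected layers ending in a
  sigmoid unit, trained on latent + static features with class-weighted
  binary cross-entropy; early stopping selects the epoch count, then the
  model is refit on train + validation at that count.
* :class:`LogisticBaseline` — a single linear layer + sigmoid (weighted
  logistic regression) on the last-block lab values + statics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from ._util import substream
from .nncore import (
    BatchNorm, Dense, Dropout, LeakyReLU, Network, ReLU, Reshape, ResBlock,
    TemporalConv, ZeroUpsample, fit_network, mse_loss, sigmoid,
    weighted_bce_loss,
)

N_BLOCKS = 9


@dataclass
class AEConfig:
    n_res_blocks: int = 3
    filters: tuple[int, ...] = (8, 16, 16)
    kernel: int = 3
    latent_dim: int = 128
    squeeze_channels: int = 8  # 1x1 channel squeeze before the bottleneck
    leaky_alpha: float = 0.1
    batchnorm: str | bool = "bottleneck"  # False | "bottleneck" | "full"
    dropout: float = 0.2
    l2: float = 1e-4
    epochs: int = 18
    batch_size: int = 128
    lr: float = 1e-3
    patience: int = 8
    holdout_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if len(self.filters) != self.n_res_blocks:
            raise ValueError("need one filter count per residual block")


@dataclass
class ClassifierConfig:
    widths: tuple[int, int, int, int] = (128, 64, 32, 16)
    dropout: float = 0.2
    l2: float = 1e-4
    epochs: int = 200
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 10
    use_class_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.widths) != 4:
            raise ValueError("the classifier has exactly four hidden layers")


def _block_lengths(n_blocks: int, n_res: int) -> list[int]:
    # stride pattern: first block keeps length, later blocks halve it
    lengths = [n_blocks]
    for i in range(n_res):
        s = 1 if i == 0 else 2
        lengths.append((lengths[-1] - 1) // s + 1 if s > 1 else lengths[-1])
    return lengths


class TemporalAutoencoder:
    """Encoder/decoder over (n_patients, n_analytes, 9) standardized grids."""

    def __init__(self, n_analytes: int, config: AEConfig | None = None):
        self.config = config or AEConfig()
        self.n_analytes = n_analytes
        cfg = self.config
        rng = substream(cfg.seed, "ae-init")
        A, k = n_analytes, cfg.kernel
        lengths = _block_lengths(N_BLOCKS, cfg.n_res_blocks)
        f = list(cfg.filters)
        self._drop_rng = substream(cfg.seed, "ae-dropout")

        act = lambda: LeakyReLU(cfg.leaky_alpha) if cfg.leaky_alpha else ReLU()
        bn_mode = cfg.batchnorm
        full_bn = bn_mode in (True, "full")

        def bn(c, always=False):
            # "bottleneck" mode normalizes only around the narrow dense path,
            # where optimization stalls; "full" normalizes every conv output
            return [BatchNorm(c)] if (full_bn or (always and bn_mode)) else []

        enc: list = [Reshape(lambda s: (-1, N_BLOCKS, 1))]
        enc += [TemporalConv(1, f[0], k, rng), *bn(f[0]), act()]
        for i in range(cfg.n_res_blocks):
            stride = 1 if i == 0 else 2
            c_in = f[i - 1] if i else f[0]
            enc.append(ResBlock(c_in, f[i], k, rng, stride=stride,
                                alpha=cfg.leaky_alpha,
                                batchnorm=full_bn))
        l_last, f_last = lengths[-1], f[-1]
        sq = cfg.squeeze_channels or f_last
        if sq != f_last:
            enc += [TemporalConv(f_last, sq, 1, rng, pad=0),
                    *bn(sq, always=True), act()]
        flat = A * l_last * sq
        enc += [
            Reshape(lambda s, A=A: (s[0] // A, A * s[1] * s[2])),
            Dropout(cfg.dropout, self._drop_rng),
            Dense(flat, cfg.latent_dim, rng),
        ]
        self._n_enc_layers = len(enc)

        dec: list = [Dense(cfg.latent_dim, flat, rng), *bn(flat, always=True),
                     act(), Reshape(lambda s, l=l_last, c=sq: (-1, l, c))]
        if sq != f_last:
            dec += [TemporalConv(sq, f_last, 1, rng, pad=0),
                    *bn(f_last, always=True), act()]
        for i in range(cfg.n_res_blocks - 1, 0, -1):
            dec += [ZeroUpsample(2), TemporalConv(f[i], f[i - 1], k, rng),
                    *bn(f[i - 1]), act()]
        dec += [TemporalConv(f[0], 1, k, rng),
                Reshape(lambda s, A=A: (s[0] // A, A, N_BLOCKS))]

        self.net = Network(enc + dec)
        self.encoder = Network(enc)
        self.history: dict | None = None

    def fit(self, X: np.ndarray, labels: np.ndarray | None = None):
        """Train by reconstruction; refuses donor-labelled rows."""
        if labels is not None and np.any(np.asarray(labels) == 1):
            raise ValueError("autoencoder must be trained on non-donor rows only")
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        rng = substream(cfg.seed, "ae-train")
        n_val = max(1, int(round(cfg.holdout_frac * len(X))))
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        self.history = fit_network(
            self.net, X[tr_idx], X[tr_idx], loss_fn=mse_loss,
            X_val=X[val_idx], y_val=X[val_idx],
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
            l2=cfg.l2, patience=cfg.patience, rng=rng,
        )
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Deterministic latent embedding (dropout off)."""
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != self.n_analytes:
            raise ValueError("analyte axis mismatch with fitted autoencoder")
        return self.encoder.forward(X, training=False)

    def reconstruction_error(self, X: np.ndarray) -> np.ndarray:
        """Per-patient mean squared reconstruction error."""
        X = np.asarray(X, dtype=np.float32)
        rec = self.net.forward(X, training=False)
        return np.mean((rec - X) ** 2, axis=(1, 2))

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, w):
        self.net.set_weights(w)


class DeepClassifier:
    """Four dense layers + sigmoid; weighted BCE; early stop then refit."""

    def __init__(self, n_features: int, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.n_features = n_features
        self.history: dict | None = None
        self.net = self._build(substream(self.config.seed, "clf-init"),
                               substream(self.config.seed, "clf-dropout"))

    def _build(self, rng, drop_rng) -> Network:
        cfg = self.config
        layers: list = []
        n_in = self.n_features
        for w in cfg.widths:
            layers += [Dense(n_in, w, rng), ReLU(),
                       Dropout(cfg.dropout, drop_rng)]
            n_in = w
        layers.append(Dense(n_in, 1, rng))  # logits; sigmoid lives in the loss
        return Network(layers)

    def fit(self, X, y, sample_weight=None, X_val=None, y_val=None,
            val_weight=None):
        """Early-stop on validation loss, then refit train+validation at the
        selected epoch count (the final-training protocol)."""
        cfg = self.config
        if len(np.unique(np.asarray(y))) < 2:
            raise ValueError("classifier requires both classes in training labels")
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng = substream(cfg.seed, "clf-train")
        self.history = fit_network(
            self.net, X, y, loss_fn=weighted_bce_loss,
            sample_weight=sample_weight, X_val=np.asarray(X_val, np.float32),
            y_val=np.asarray(y_val, np.float32), val_weight=val_weight,
            epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
            l2=cfg.l2, patience=cfg.patience, rng=rng,
        )
        best = self.history["best_epoch"]
        # fresh init + combined data at the selected budget
        self.net = self._build(substream(cfg.seed, "clf-init"),
                               substream(cfg.seed, "clf-dropout"))
        Xc = np.concatenate([X, np.asarray(X_val, np.float32)])
        yc = np.concatenate([y, np.asarray(y_val, np.float32)])
        wc = None
        if sample_weight is not None:
            wc = np.concatenate([sample_weight, val_weight])
        self.history["refit_epochs"] = best
        fit_network(
            self.net, Xc, yc, loss_fn=weighted_bce_loss, sample_weight=wc,
            epochs=best, batch_size=cfg.batch_size, lr=cfg.lr, l2=cfg.l2,
            patience=None, rng=substream(cfg.seed, "clf-refit"),
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != self.n_features:
            raise ValueError("feature count mismatch")
        logits = self.net.forward(X, training=False)
        return sigmoid(logits).ravel().astype(float)

    def get_weights(self):
        return self.net.get_weights()

    def set_weights(self, w):
        self.net.set_weights(w)


class LogisticBaseline:
    """Weighted logistic regression on block-9 values + statics."""

    def __init__(self, l2_c: float = 1e4, seed: int = 0):
        self.model = LogisticRegression(C=l2_c, max_iter=5000, solver="lbfgs")
        self.seed = seed

    def fit(self, X, y, sample_weight=None):
        if len(np.unique(np.asarray(y))) < 2:
            raise ValueError("baseline requires both classes in training labels")
        self.model.fit(np.asarray(X, float), np.asarray(y, int),
                       sample_weight=sample_weight)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self.model.intercept_[0])

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, float))[:, 1]


def latent_probe_auroc(latents, labels, seed: int = 0) -> float:
    """Linear-separability probe of the latent space (diagnostic)."""
    from .metrics import auroc

    lr = LogisticRegression(max_iter=2000)
    lr.fit(latents, labels)
    return auroc(lr.predict_proba(latents)[:, 1], labels)
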