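"""Small trainable convolutional networks used as pluggable feature extractors.

The pipeline needs classifiers that (a) emit per-label sigmoid probabilities,
(b) expose their final convolutional feature maps and the global-average-pooled
(GAP) embedding derived from them, and (c) provide gradients of any output
with respect to those maps, so that class-activation saliency can be computed.
:class:`FixtureCNN` is a compact NumPy implementation of exactly that contract:
a stack of ``conv(3x3, same) -> ReLU -> 2x2 average pool`` blocks, a GAP layer
and a dense sigmoid head, trained with Adam on binary cross-entropy.

All computation is dense NumPy; images of side 64 with two or three blocks
train in seconds per epoch on one CPU, which is the scale the synthetic
benchmarks in this package use.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

__all__ = ["FixtureCNN", "TrainHistory"]

_DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, sd, size=shape).astype(_DTYPE)


class _Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = _glorot(rng, c_in * 9, c_out, (c_in * 9, c_out))
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (n, c, h, w, 3, 3) -> (n*h*w, c*9)
        cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)
        y = cols @ self.W + self.b
        if keep:
            self._cols, self._shape = cols, (n, c, h, w)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, c, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.c_out)
        dW = self._cols.T @ dyf
        db = dyf.sum(axis=0)
        # dx is the full correlation of dy with the spatially flipped kernels
        wt = self.W.reshape(c, 3, 3, self.c_out)[:, ::-1, ::-1, :]
        wt = np.ascontiguousarray(wt.transpose(3, 1, 2, 0)).reshape(self.c_out * 9, c)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = sliding_window_view(dyp, (3, 3), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, self.c_out * 9)
        dx = (cols @ wt).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        self._cols = None
        return dx, dW, db


def _avg_pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avg_pool2_back(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * np.asarray(0.25, dtype=dy.dtype)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainHistory:
    """Per-epoch training record (loss, learning rate, validation AUC)."""

    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int | None = None


class FixtureCNN:
    """Conv blocks -> GAP -> dense sigmoid head, with explicit gradients.

    Parameters
    ----------
    n_labels : number of sigmoid outputs.
    in_channels : input channels (3 for channel-replicated grayscale).
    widths : channel count of each conv block; the last entry is the
        embedding dimension (one GAP value per final-conv channel).
    seed : seed for weight initialization.
    """

    def __init__(self, n_labels: int, in_channels: int = 3,
                 widths: tuple[int, ...] = (8, 16), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_labels = int(n_labels)
        self.in_channels = int(in_channels)
        self.widths = tuple(int(v) for v in widths)
        self.convs: list[_Conv3x3] = []
        c = in_channels
        for c_out in self.widths:
            self.convs.append(_Conv3x3(c, c_out, rng))
            c = c_out
        self.embed_dim = c
        self.Wd = _glorot(rng, c, n_labels, (n_labels, c))
        self.bd = np.zeros(n_labels, dtype=_DTYPE)

    # ---------------------------------------------------------------- forward

    def _features(self, x: np.ndarray, keep: bool = False) -> tuple[np.ndarray, list]:
        """Run the conv trunk; returns final conv maps (pre-GAP) and caches."""
        a = np.ascontiguousarray(x, dtype=_DTYPE)
        caches = []
        for conv in self.convs:
            z = conv.forward(a, keep=keep)
            mask = z > 0
            a = z * mask
            caches.append(mask if keep else None)
            a = _avg_pool2(a)
        return a, caches

    @staticmethod
    def _as_batch(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return x[None] if x.ndim == 3 else x

    def conv_maps(self, x: np.ndarray) -> np.ndarray:
        """Final convolutional feature maps, shape (n, C, h, w)."""
        maps, _ = self._features(self._as_batch(x))
        return maps

    def embed(self, x: np.ndarray) -> np.ndarray:
        """GAP embedding: channel-wise spatial mean of the final conv maps."""
        return self.conv_maps(x).mean(axis=(2, 3))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.embed(x) @ self.Wd.T + self.bd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-label sigmoid probabilities, shape (n, n_labels)."""
        return _sigmoid(self.logits(x))

    def conv_grad(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """Gradient of the class logit w.r.t. the final conv maps.

        With a GAP head the gradient of ``logit_c`` w.r.t. map channel k is
        the dense weight ``Wd[c, k]`` spread uniformly over the h*w positions.
        Returned with shape (n, C, h, w), matching :meth:`conv_maps`.
        """
        maps, _ = self._features(self._as_batch(x))
        n, c, h, w = maps.shape
        g = self.Wd[class_index].astype(_DTYPE) / (h * w)
        return np.broadcast_to(g[None, :, None, None], (n, c, h, w)).copy()

    # --------------------------------------------------------------- training

    def _params(self) -> list[np.ndarray]:
        ps = []
        for conv in self.convs:
            ps += [conv.W, conv.b]
        ps += [self.Wd, self.bd]
        return ps

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, list[np.ndarray]]:
        n = x.shape[0]
        maps, relu_masks = self._features(x, keep=True)
        _, c, h, w = maps.shape
        a = maps.mean(axis=(2, 3))
        z = a @ self.Wd.T + self.bd
        p = _sigmoid(z)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
        dz = (p - y.astype(p.dtype)) / (n * self.n_labels)
        dWd = dz.T @ a
        dbd = dz.sum(axis=0)
        da = dz @ self.Wd
        dmaps = np.broadcast_to(da[:, :, None, None] / (h * w), maps.shape).astype(_DTYPE)
        grads_rev = [dbd, dWd]
        d = dmaps
        for conv, mask in zip(reversed(self.convs), reversed(relu_masks)):
            d = _avg_pool2_back(d)
            d = d * mask
            d, dW, db = conv.backward(d)
            grads_rev += [db, dW]
        return loss, list(reversed(grads_rev))

    def fit(self, X: np.ndarray, y: np.ndarray, *,
            epochs: int = 5, lr: float = 1e-3, lr_decay: float = 1.0,
            batch_size: int = 16, seed: int = 0,
            val: tuple[np.ndarray, np.ndarray] | None = None,
            patience: int | None = None) -> TrainHistory:
        """Train with Adam on binary cross-entropy.

        ``lr_decay`` multiplies the learning rate after every epoch
        (``lr_decay=0.1`` reproduces the divide-by-ten-per-epoch schedule).
        When ``val`` is given, validation mean AUC is tracked each epoch,
        the best-epoch weights are restored at the end, and training stops
        early after ``patience`` epochs without improvement.
        """
        rng = np.random.default_rng(seed)
        X = np.ascontiguousarray(X, dtype=_DTYPE)
        y = np.asarray(y, dtype=_DTYPE).reshape(X.shape[0], self.n_labels)
        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        hist = TrainHistory()
        best_auc, best_state, since_best = -np.inf, None, 0
        cur_lr = lr
        for epoch in range(1, epochs + 1):
            order = rng.permutation(X.shape[0])
            losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self._loss_and_grads(X[idx], y[idx])
                losses.append(loss)
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    mhat = mi / (1 - b1 ** t)
                    vhat = vi / (1 - b2 ** t)
                    p -= (cur_lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)
            hist.epoch.append(epoch)
            hist.lr.append(cur_lr)
            hist.train_loss.append(float(np.mean(losses)))
            if val is not None:
                auc = self._mean_auc(*val)
                hist.val_auc.append(auc)
                if auc > best_auc:
                    best_auc, since_best = auc, 0
                    best_state = copy.deepcopy(params)
                    hist.best_epoch = epoch
                else:
                    since_best += 1
                    if patience is not None and since_best >= patience:
                        break
            cur_lr *= lr_decay
        if best_state is not None:
            for p, s in zip(params, best_state):
                p[...] = s
        return hist

    def _mean_auc(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        y = np.asarray(y).reshape(p.shape)
        aucs = [roc_auc_score(y[:, j], p[:, j])
                for j in range(self.n_labels) if len(np.unique(y[:, j])) == 2]
        return float(np.mean(aucs)) if aucs else 0.5

    # ------------------------------------------------------------------ misc

    def replace_head(self, n_labels: int, seed: int = 0, init_sd: float = 1e-4) -> None:
        """Swap the dense head for a fresh one with ``n_labels`` outputs.

        The new head is randomly initialized at small scale (``init_sd``) so
        that a short low-learning-rate fine-tuning run is signal-driven
        rather than dominated by the initialization.
        """
        rng = np.random.default_rng(seed)
        self.n_labels = int(n_labels)
        self.Wd = rng.normal(0.0, init_sd, size=(n_labels, self.embed_dim)).astype(_DTYPE)
        self.bd = np.zeros(n_labels, dtype=_DTYPE)

    def copy(self) -> "FixtureCNN":
        return copy.deepcopy(self)
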