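"""A small convolutional network for connectivity images, in plain numpy.

Architecture (fixed by configuration, defaults below):

    conv 32@3x3 (stride 1, pad 1) -> ReLU ->
    conv 32@3x3 (stride 1, pad 1) -> ReLU ->
    maxpool 2x2 (stride 2) -> flatten ->
    FC 512 -> ReLU -> dropout 0.5 -> FC 2 -> softmax

For a 90 x 90 single-channel input the pooled feature map is 45 x 45 x 32,
i.e. a flattened dimension of 64,800.  Training uses Adam (lr 1e-3, betas
0.9/0.999), Xavier (Glorot uniform) initialization, cross-entropy loss,
15 epochs with batch size 30, and keep-best early stopping: the full
epoch budget is run and the weights from the epoch with the best
validation accuracy are returned.

Convolutions are evaluated as im2col + matrix products (forward, weight
gradient and input gradient alike), so the heavy lifting is BLAS sgemm in
float32.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class CNNConfig:
    in_channels: int = 1
    conv_filters: int = 32
    kernel: int = 3
    stride: int = 1
    pad: int = 1
    n_conv: int = 2
    pool: int = 2
    pool_stride: int = 2
    fc_hidden: int = 512
    n_classes: int = 2
    dropout_p: float = 0.5
    lr: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    epochs: int = 15
    batch: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.stride != 1 or self.pad != (self.kernel - 1) // 2:
            raise ValueError("convolutions must preserve spatial resolution")


def softmax(v: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis (log-sum-exp shifted)."""
    v = np.asarray(v, dtype=np.float64)
    z = v - v.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x_padded: np.ndarray, k: int, out: np.ndarray | None = None) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N*Ho*Wo, k*k*C) patch matrix, row-major patches.

    Internally the network works in NHWC layout so that the convolution
    output and every gradient are contiguous without transposition; the
    patch axes are ordered (kH, kW, C) so the materializing copy streams
    along contiguous memory, and ``out`` lets callers reuse the buffer.
    """
    v = np.lib.stride_tricks.sliding_window_view(x_padded, (k, k), axis=(1, 2))
    # window axes are appended last: N, Ho, Wo, C, kH, kW
    v = v.transpose(0, 1, 2, 4, 5, 3)
    n, ho, wo = v.shape[:3]
    if out is None or out.shape != v.shape or out.dtype != v.dtype:
        out = np.empty(v.shape, dtype=v.dtype)
    np.copyto(out, v)
    return out.reshape(n * ho * wo, -1)


class Conv2D:
    """3x3 same-padding convolution evaluated as an im2col matrix product."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.W = _glorot_uniform(rng, fan_in, fan_out, (c_in * k * k, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None
        self._bufs: dict = {}  # reused im2col buffers, keyed by role+shape

    def params(self):
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    is_first = False  # the input layer skips its input gradient

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        pad = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        key = ("fwd", x.shape, train)
        cols = _im2col(xp, self.k, out=self._bufs.get(key))
        self._bufs[key] = cols.reshape(n, h, w, self.k, self.k, c)
        y = cols @ self.W + self.b
        if train:
            self._cache = (cols, (n, h, w))
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray):
        cols, (n, h, w) = self._cache
        dym = dy.reshape(-1, self.c_out)
        dW = cols.T @ dym
        db = dym.sum(axis=0)
        self._cache = None
        if self.is_first:
            return None, [dW, db]
        # input gradient: correlate dy with spatially flipped, channel-swapped W
        k, pad = self.k, (self.k - 1) // 2
        w4 = self.W.reshape(k, k, self.c_in, self.c_out)
        w_back = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2)
        ).reshape(k * k * self.c_out, self.c_in)
        dyp = np.pad(dy, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        key = ("bwd", dy.shape)
        cols2 = _im2col(dyp, k, out=self._bufs.get(key))
        self._bufs[key] = cols2.reshape(n, h, w, k, k, self.c_out)
        dx = (cols2 @ w_back).reshape(n, h, w, self.c_in)
        return dx, [dW, db]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask, []


class MaxPool2x2:
    """2x2 max pooling, stride 2; requires even spatial dimensions."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x, train):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"max pooling 2x2/2 requires even spatial size, got {h}x{w}"
            )
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = r.max(axis=(2, 4))
        if train:
            # subgradient split evenly among tied maxima
            mask = r == y[:, :, None, :, None, :]
            inv_counts = (
                1.0 / mask.sum(axis=(2, 4), keepdims=True)
            ).astype(np.float32)
            self._cache = (mask, inv_counts, x.shape)
        return y

    def backward(self, dy):
        mask, inv_counts, shape = self._cache
        g = mask * (dy[:, :, None, :, None, :] * inv_counts)
        return g.reshape(shape), []


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape), []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        return dy @ self.W.T, [dW, db]


class Dropout:
    """Inverted dropout: active in training, identity at evaluation."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask, []


class CNNModel:
    """Layer stack with shared dropout/shuffle RNG, seeded at build time."""

    def __init__(self, layers: list, cfg: CNNConfig, side: int, rng: np.random.Generator):
        self.layers = layers
        self.cfg = cfg
        self.side = side
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out  # logits

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        d = dlogits
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        return grads

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.params(), values):
            p[...] = v

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        x = _as_nhwc(x, self.cfg.in_channels)
        out = [softmax(self.forward(x[s : s + batch])) for s in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.empty((0, self.cfg.n_classes))


def _as_nhwc(x: np.ndarray, in_channels: int) -> np.ndarray:
    """Accept (N, side, side), (N, side, side, C) or (N, C, side, side)."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, :, :, None]
    elif x.ndim == 4 and x.shape[1] in (1, 3) and x.shape[-1] not in (1, 3):
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
    if x.ndim != 4 or x.shape[-1] != in_channels:
        raise ValueError(f"expected {in_channels}-channel image batch, got {x.shape}")
    return np.ascontiguousarray(x)


def build_model(cfg: CNNConfig, side: int = 90) -> CNNModel:
    """Assemble the network for ``side x side`` inputs.

    The single pooling stage halves the spatial size, so ``side`` must be
    even; identical config seeds give identical initial weights.
    """
    if side % cfg.pool:
        raise ValueError(
            f"input side {side} is not divisible by the pooling window "
            f"{cfg.pool}; pad or crop the images first"
        )
    rng = np.random.default_rng(cfg.seed)
    layers: list = []
    c_in = cfg.in_channels
    for li in range(cfg.n_conv):
        conv = Conv2D(c_in, cfg.conv_filters, cfg.kernel, rng)
        conv.is_first = li == 0
        layers += [conv, ReLU()]
        c_in = cfg.conv_filters
    layers.append(MaxPool2x2())
    pooled = side // cfg.pool_stride
    flat_dim = pooled * pooled * cfg.conv_filters
    layers += [
        Flatten(),
        Dense(flat_dim, cfg.fc_hidden, rng),
        ReLU(),
        Dropout(cfg.dropout_p, rng),
        Dense(cfg.fc_hidden, cfg.n_classes, rng),
    ]
    return CNNModel(layers, cfg, side, rng)


def flattened_dimension(cfg: CNNConfig, side: int) -> int:
    """Dimension entering the first fully connected layer."""
    pooled = side // cfg.pool_stride
    return pooled * pooled * cfg.conv_filters


try:  # fused single-pass update; falls back to vectorized numpy
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _adam_update(p, g, m, v, b1, b2, alpha, inv_sqrt_b2t, eps):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= alpha * m[i] / (np.sqrt(v[i]) * inv_sqrt_b2t + eps)
except Exception:  # numba unavailable
    _adam_update = None


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float, b1: float, b2: float,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        alpha = np.float32(self.lr / b1t)
        inv_sqrt_b2t = np.float32(1.0 / np.sqrt(b2t))
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float32)
            if _adam_update is not None:
                _adam_update(p.ravel(), g.ravel(), m.ravel(), v.ravel(),
                             np.float32(self.b1), np.float32(self.b2),
                             alpha, inv_sqrt_b2t, np.float32(self.eps))
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            np.square(g, out=g)
            v *= self.b2
            v += (1 - self.b2) * g
            denom = np.sqrt(v, out=g)
            denom *= inv_sqrt_b2t
            denom += self.eps
            np.divide(m, denom, out=denom)
            denom *= alpha
            p -= denom


def _loss_and_dlogits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy on softmax outputs and its gradient w.r.t. logits."""
    logits = logits.astype(np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(y)
    loss = -log_probs[np.arange(n), y].mean()
    d = np.exp(log_probs)
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(np.float32)


@dataclass
class TrainedModel:
    model: CNNModel
    history: dict
    best_epoch: int
    config: CNNConfig
    seed: int


def train(
    model: CNNModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    cfg: CNNConfig | None = None,
) -> TrainedModel:
    """Adam training with keep-best early stopping.

    Runs the full epoch budget and restores the weights from the epoch with
    the highest validation accuracy (earliest epoch wins ties).  With no
    validation set, early stopping is disabled with a warning and the final
    weights are kept.  Deterministic for a fixed model seed and data order.
    """
    cfg = cfg or model.cfg
    x_tr = _as_nhwc(train_set[0], cfg.in_channels)
    y_tr = np.asarray(train_set[1], dtype=np.int64)
    if val_set is not None and len(val_set[1]) > 0:
        x_val = _as_nhwc(val_set[0], cfg.in_channels)
        y_val = np.asarray(val_set[1], dtype=np.int64)
    else:
        if val_set is not None and len(val_set[1]) == 0:
            val_set = None
        if val_set is None:
            warnings.warn("empty validation set: early stopping disabled", stacklevel=2)
        x_val = y_val = None

    opt = Adam(model.params(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_acc, best_epoch, best_params = -np.inf, -1, None

    for epoch in range(cfg.epochs):
        order = model.rng.permutation(len(y_tr))
        losses = []
        for s in range(0, len(order), cfg.batch):
            idx = order[s : s + cfg.batch]
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = _loss_and_dlogits(logits, y_tr[idx])
            grads = model.backward(dlogits)
            opt.step(model.params(), grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None:
            logits = model.forward(x_val, train=False)
            vloss, _ = _loss_and_dlogits(logits, y_val)
            vacc = float((logits.argmax(axis=1) == y_val).mean())
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(vacc)
            if vacc > best_acc:
                best_acc, best_epoch = vacc, epoch
                best_params = [p.copy() for p in model.params()]
        else:
            history["val_loss"].append(np.nan)
            history["val_accuracy"].append(np.nan)

    if best_params is not None:
        model.set_params(best_params)
    else:
        best_epoch = cfg.epochs - 1
    return TrainedModel(model, history, best_epoch, cfg, cfg.seed)


def save_model(trained: TrainedModel, path) -> None:
    """Checkpoint layout: ``<path>.npz`` holds ``param_000..`` weight arrays;
    ``<path>.json`` holds the config, input side, history and best epoch."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    model = trained.model
    np.savez(path.with_suffix(".npz"),
             **{f"param_{i:03d}": p for i, p in enumerate(model.params())})
    meta = {
        "config": asdict(trained.config),
        "side": model.side,
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "seed": trained.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_model(path) -> TrainedModel:
    """Rebuild a checkpointed model (architecture from config, then weights)."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = CNNConfig(**meta["config"])
    model = build_model(cfg, side=meta["side"])
    with np.load(path.with_suffix(".npz")) as npz:
        model.set_params([npz[f"param_{i:03d}"] for i in range(len(model.params()))])
    return TrainedModel(model, meta["history"], meta["best_epoch"], cfg, meta["seed"])


@dataclass
class EvalResult:
    accuracy: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate(model: CNNModel, x: np.ndarray, y: np.ndarray) -> EvalResult:
    """Accuracy at argmax plus ROC/AUC from the positive-class probability."""
    x = _as_nhwc(x, model.cfg.in_channels)
    y = np.asarray(y, dtype=np.int64)
    proba = model.predict_proba(x)
    accuracy = float((proba.argmax(axis=1) == y).mean())
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set contains a single class")
    fpr, tpr, _ = _sk_roc_curve(y, proba[:, 1])
    return EvalResult(accuracy, fpr, tpr, float(_sk_auc(fpr, tpr)))
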