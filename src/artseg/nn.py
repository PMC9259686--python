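"""Minimal CPU neural-network engine used by the classifier and the U-Net.

Implements exactly the pieces the segmentation pipeline needs: 2-D
convolutions (im2col + GEMM), ReLU, 2x2 max pooling, nearest-neighbour x2
upsampling, dense layers, Adam, and a reduce-on-plateau learning-rate
schedule (initial rate divided by a fixed factor when validation loss has
not improved for `lr_patience_epochs` consecutive epochs).

All tensors are float32 NCHW. Layers cache what their backward pass needs;
a layer instance is therefore not re-entrant, which is fine for the strictly
sequential training loops used here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# training configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimisation settings shared by the classifier and the segmenter.

    Defaults follow the training recipe of the pipeline: Adam on binary
    cross-entropy, initial learning rate 0.002 reduced by a factor of 10
    when the validation loss has not improved for 10 consecutive epochs.
    """

    initial_learning_rate: float = 0.002
    epochs: int = 150
    lr_reduction_factor: float = 10.0
    lr_patience_epochs: int = 10
    batch_size: int = 16
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("learning rate and epochs must be positive")
        if self.lr_reduction_factor <= 1:
            raise ValueError("lr_reduction_factor must exceed 1")
        if not (0 < self.lr_patience_epochs < self.epochs):
            raise ValueError("patience must be positive and below epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class: parameters plus cached-state forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padding convolution with square kernels (3x3 or 1x1 here)."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        if ksize % 2 != 1:
            raise ValueError("only odd kernel sizes supported")
        self.cin, self.cout, self.k = cin, cout, ksize
        self.w = he_init(rng, (cout, cin * ksize * ksize), cin * ksize * ksize)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (N, C, H, W, k, k) view -> (N*H*W, C*k*k) matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        out = cols @ self.w.T + self.b
        self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = self._xshape
        p = self.k // 2
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        g2 = np.ascontiguousarray(g2, dtype=np.float32)
        self.dw[...] = g2.T @ self._cols
        self.db[...] = g2.sum(axis=0)
        dcols = g2 @ self.w  # (N*H*W, C*k*k)
        dcols = dcols.reshape(n, h, w, self.cin, self.k, self.k)
        dxp = np.zeros((n, self.cin, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(g, self._arg[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    """Nearest-neighbour upsampling by 2 in both spatial axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = he_init(rng, (cout, cin), cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return (grad @ self.w).astype(np.float32)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; labels are integer class ids."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), (g / n).astype(np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Pixel-mean binary cross-entropy on logits (numerically stable)."""
    x = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    g = (sigmoid(x) - t) / x.size
    return float(loss.mean()), g.astype(np.float32)


# ---------------------------------------------------------------------------
# optimiser and training loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Model:
    """Base class for the explicit-graph models (classifier, U-Net)."""

    layers: list[Layer]

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    def save(self, directory: str | Path, meta: dict | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **{f"p{i}": p for i, p in enumerate(self.params())})
        sidecar = {"class": type(self).__name__, "meta": meta or {}}
        (d / "model.json").write_text(json.dumps(sidecar, indent=2))

    def load_weights(self, directory: str | Path) -> None:
        with np.load(Path(directory) / "weights.npz") as z:
            self.set_weights([z[f"p{i}"] for i in range(len(z.files))])


@dataclass
class History:
    """Per-epoch record of a training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return asdict(self)


def fit(model: Model,
        forward_loss: Callable[[np.ndarray, np.ndarray], tuple[float, Callable[[], None]]],
        eval_loss: Callable[[np.ndarray, np.ndarray], float],
        x_train: np.ndarray, y_train: np.ndarray,
        x_val: np.ndarray, y_val: np.ndarray,
        config: TrainConfig) -> History:
    """Generic minibatch loop with plateau LR schedule and best-weight restore.

    `forward_loss(xb, yb)` runs the forward pass and returns
    `(loss, backward_fn)`; calling `backward_fn` populates the gradients.
    Validation loss is computed after every epoch; when it fails to improve
    for `lr_patience_epochs` consecutive epochs the learning rate is divided
    by `lr_reduction_factor` (taking effect from the next epoch) and the
    stagnation counter resets. The weights with the best validation loss
    are restored at the end.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), config.initial_learning_rate)
    hist = History()
    best_val = np.inf
    best_weights = model.get_weights()
    stagnant = 0
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, backward = forward_loss(x_train[idx], y_train[idx])
            backward()
            opt.step(model.grads())
            losses.append(loss)
        vlosses = [eval_loss(x_val[s:s + config.batch_size], y_val[s:s + config.batch_size])
                   for s in range(0, x_val.shape[0], config.batch_size)]
        vloss = float(np.mean(vlosses))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(vloss)
        hist.learning_rate.append(opt.lr)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_weights = model.get_weights()
            hist.best_epoch = epoch
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.lr_patience_epochs:
                opt.lr /= config.lr_reduction_factor
                stagnant = 0
    model.set_weights(best_weights)
    return hist
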