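"""Minimal numpy neural-network core: conv/pool/dense layers, softmax
cross-entropy, Adam, early stopping.

Built in-house because the execution environment ships no deep-learning
framework. Layers operate on NCHW batches; everything is float64 and
seeded, so runs are bit-reproducible. Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_PROB = 1e-7  # probability clip shared with metrics.cross_entropy_loss


class ConfigurationError(ValueError):
    """Layer/shape incompatibility."""


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""


class Layer:
    trainable = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: str = "he"):
        std = np.sqrt(2.0 / n_in) if scale == "he" else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*kh*kw) patches under same-padding."""
    n, c, h, w = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, c, kh, kw, h, w))
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.transpose(0, 4, 5, 1, 2, 3).reshape(n * h * w, c * kh * kw)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = x_shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    cols = cols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, ph : ph + h, pw : pw + w]


class Conv2D(Layer):
    """Same-padded, stride-1 convolution; odd kernel sizes only."""

    trainable = True

    def __init__(self, in_channels: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError(f"Conv2D kernel must be odd, got {kernel}")
        fan_in = in_channels * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(filters, in_channels, kh, kw))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = (kh, kw)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        kh, kw = self.kernel
        self._cols = _im2col(x, kh, kw)
        n, _, h, w = x.shape
        f = self.W.shape[0]
        out = self._cols @ self.W.reshape(f, -1).T + self.b
        return out.reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        n, f, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        self.dW[...] = (g.T @ self._cols).reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        dcols = g @ self.W.reshape(f, -1)
        return _col2im(dcols, self._x_shape, kh, kw)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols are cropped."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = self.pool
        if ph > h or pw > w:
            raise ConfigurationError(
                f"pool {self.pool} larger than feature map ({h}, {w})"
            )
        oh, ow = h // ph, w // pw
        xc = x[:, :, : oh * ph, : ow * pw]
        self._x_shape = x.shape
        windows = xc.reshape(n, c, oh, ph, ow, pw)
        flat = windows.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, ph * pw)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        ph, pw = self.pool
        oh, ow = h // ph, w // pw
        dflat = np.zeros((n, c, oh, ow, ph * pw))
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._x_shape)
        dx[:, :, : oh * ph, : ow * pw] = (
            dflat.reshape(n, c, oh, ow, ph, pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, oh * ph, ow * pw)
        )
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    Identical to the printed binary loss
    -1/(m+n)[sum log f(x+) + sum log(1 - f(x-))] when class 1 is
    positive, with probabilities clipped at EPS_PROB.
    """
    p = softmax(logits)
    n = logits.shape[0]
    picked = np.clip(p[np.arange(n), y], EPS_PROB, 1 - EPS_PROB)
    loss = float(-np.log(picked).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_trainable_layers(self) -> int:
        return sum(1 for layer in self.layers if layer.trainable)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class EarlyStopping:
    """Stop when the monitored value hasn't improved for `patience` epochs."""

    patience: int = 10
    min_delta: float = 0.0
    best: float = np.inf
    best_epoch: int = -1
    best_weights: list[np.ndarray] | None = None
    wait: int = 0

    def update(self, value: float, epoch: int, model: Sequential) -> bool:
        """Record `value`; return True when training should stop."""
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.best_weights = model.get_weights()
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience

    def restore(self, model: Sequential) -> None:
        if self.best_weights is not None:
            model.set_weights(self.best_weights)


@dataclass
class TrainingTrace:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.train_loss)


def fit(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_epochs: int = 100,
    batch_size: int = 32,
    lr: float = 0.01,
    patience: int = 10,
    seed: int = 0,
) -> TrainingTrace:
    """Mini-batch Adam training with early stopping on validation loss.

    Best weights (by validation loss) are restored on exit.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    stopper = EarlyStopping(patience=patience)
    trace = TrainingTrace()
    n = X.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            logits = model.forward(X[batch])
            loss, grad = softmax_ce(logits, y[batch])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            model.backward(grad)
            opt.step(model.grads)

        tr_loss, tr_grad = softmax_ce(model.forward(X), y)
        tr_acc = float((model.predict_proba(X).argmax(axis=1) == y).mean())
        va_loss, _ = softmax_ce(model.forward(X_val), y_val)
        va_acc = float((model.predict_proba(X_val).argmax(axis=1) == y_val).mean())
        trace.train_loss.append(tr_loss)
        trace.train_acc.append(tr_acc)
        trace.val_loss.append(va_loss)
        trace.val_acc.append(va_acc)
        if stopper.update(va_loss, epoch, model):
            trace.stopped_epoch = epoch
            break
    stopper.restore(model)
    trace.best_epoch = stopper.best_epoch
    return trace
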