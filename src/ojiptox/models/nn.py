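"""Minimal feed-forward layer framework on numpy.

Implements exactly the layer vocabulary the classifier architectures need —
Dense, BatchNorm, Dropout, Conv1D/Conv2D ("same" padding, stride 1),
MaxPool1D/2D, Flatten, ReLU — with Glorot-uniform initialization, softmax
cross-entropy loss and the Adam optimizer (default learning rate 0.001).
Computation is single precision by default (float32, the customary deep
learning precision; float64 selectable) and bit-deterministic for a given
seed.  Layout conventions: channels last; 1D inputs are (N, L, C),
2D inputs (N, H, W, C), dense inputs (N, D).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "ReLU", "Dropout", "BatchNorm", "Flatten",
    "Conv1D", "MaxPool1D", "Conv2D", "MaxPool2D",
    "Sequential", "layer_census",
]


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: subclasses define build/forward/backward; params mirror grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.built = False

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        self.built = True
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, units: int) -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be >= 1")
        self.units = units

    def build(self, input_shape, rng):
        (d,) = input_shape
        self.params["W"] = _glorot_uniform(rng, (d, self.units), d, self.units)
        self.params["b"] = np.zeros(self.units)
        self.built = True
        return (self.units,)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout layer has no generator; fit the model")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Normalize per channel (last axis) over batch and spatial axes."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.built = True
        return input_shape

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"] * self._inv_std / self._m
        return g * (
            self._m * grad
            - self.grads["beta"]
            - self._xhat * self.grads["gamma"]
        )


class Flatten(Layer):
    def build(self, input_shape, rng):
        self.built = True
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """Stride-1 "same" convolution on (N, L, C) inputs."""

    def __init__(self, filters: int, kernel_size: int = 3) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.filters = filters
        self.k = kernel_size

    def build(self, input_shape, rng):
        length, c = input_shape
        fan_in, fan_out = self.k * c, self.k * self.filters
        self.params["W"] = _glorot_uniform(rng, (self.k, c, self.filters), fan_in, fan_out)
        self.params["b"] = np.zeros(self.filters)
        self.built = True
        return (length, self.filters)

    def forward(self, x, training):
        n, L, c = x.shape
        pad = (self.k - 1) // 2
        xp = np.zeros((n, L + 2 * pad, c), dtype=x.dtype)
        xp[:, pad : pad + L, :] = x
        self._xp, self._L = xp, L
        out = np.broadcast_to(self.params["b"], (n, L, self.filters)).copy()
        for j in range(self.k):
            patch = xp[:, j : j + L, :].reshape(-1, c)
            out += (patch @ self.params["W"][j]).reshape(n, L, self.filters)
        return out

    def backward(self, grad):
        n, L, f = grad.shape
        c = self._xp.shape[2]
        pad = (self.k - 1) // 2
        g2 = grad.reshape(-1, f)
        self.grads["W"] = np.empty_like(self.params["W"])
        self.grads["b"] = grad.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            patch = self._xp[:, j : j + L, :].reshape(-1, c)
            self.grads["W"][j] = patch.T @ g2
            dxp[:, j : j + L, :] += (g2 @ self.params["W"][j].T).reshape(n, L, c)
        return dxp[:, pad : pad + L, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def build(self, input_shape, rng):
        length, c = input_shape
        self.built = True
        return (length // self.pool, c)

    def forward(self, x, training):
        n, L, c = x.shape
        L2 = L // self.pool
        self._in_shape = x.shape
        xr = x[:, : L2 * self.pool, :].reshape(n, L2, self.pool, c)
        self._arg = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, L, c = self._in_shape
        L2 = L // self.pool
        dxr = np.zeros((n, L2, self.pool, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((n, L, c), dtype=grad.dtype)
        dx[:, : L2 * self.pool, :] = dxr.reshape(n, L2 * self.pool, c)
        return dx


class Conv2D(Layer):
    """Stride-1 "same" convolution on (N, H, W, C) inputs."""

    def __init__(self, filters: int, kernel_size: int = 3) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.filters = filters
        self.k = kernel_size

    def build(self, input_shape, rng):
        h, w, c = input_shape
        fan_in = self.k * self.k * c
        fan_out = self.k * self.k * self.filters
        self.params["W"] = _glorot_uniform(
            rng, (self.k, self.k, c, self.filters), fan_in, fan_out
        )
        self.params["b"] = np.zeros(self.filters)
        self.built = True
        return (h, w, self.filters)

    def forward(self, x, training):
        n, h, w, c = x.shape
        pad = (self.k - 1) // 2
        xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
        xp[:, pad : pad + h, pad : pad + w, :] = x
        self._xp, self._hw = xp, (h, w)
        out = np.broadcast_to(self.params["b"], (n, h, w, self.filters)).copy()
        for i in range(self.k):
            for j in range(self.k):
                patch = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                out += (patch @ self.params["W"][i, j]).reshape(n, h, w, self.filters)
        return out

    def backward(self, grad):
        n, h, w, f = grad.shape
        c = self._xp.shape[3]
        pad = (self.k - 1) // 2
        g2 = grad.reshape(-1, f)
        self.grads["W"] = np.empty_like(self.params["W"])
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                patch = self._xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                self.grads["W"][i, j] = patch.T @ g2
                dxp[:, i : i + h, j : j + w, :] += (
                    g2 @ self.params["W"][i, j].T
                ).reshape(n, h, w, c)
        return dxp[:, pad : pad + h, pad : pad + w, :]


class MaxPool2D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def build(self, input_shape, rng):
        h, w, c = input_shape
        self.built = True
        return (h // self.pool, w // self.pool, c)

    def forward(self, x, training):
        p = self.pool
        n, h, w, c = x.shape
        h2, w2 = h // p, w // p
        self._in_shape = x.shape
        xr = (
            x[:, : h2 * p, : w2 * p, :]
            .reshape(n, h2, p, w2, p, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, p * p)
        )
        self._arg = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.pool
        n, h, w, c = self._in_shape
        h2, w2 = h // p, w // p
        dxr = np.zeros((n, h2, w2, c, p * p), dtype=grad.dtype)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        dx[:, : h2 * p, : w2 * p, :] = (
            dxr.reshape(n, h2, w2, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * p, w2 * p, c)
        )
        return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, layers) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for layer in layers:
            for name, p in layer.params.items():
                key = (id(layer), name)
                g = layer.grads[name]
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[key] = (m, v)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A feed-forward stack trained with Adam on softmax cross-entropy.

    The final layer must output one logit per class (no explicit softmax
    layer: predict_proba applies it).  ``fit`` is deterministic for a given
    seed; there is no validation split and no early stopping.
    """

    def __init__(self, layers: list[Layer], dtype: str = "float32") -> None:
        self.layers = layers
        self.dtype = np.dtype(dtype)
        self.built = False
        self.history_: list[float] = []

    def build(self, input_shape: tuple, seed: int = 0) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        shape = tuple(input_shape)
        for layer in self.layers:
            shape = layer.build(shape, rng)
            for name in layer.params:
                layer.params[name] = layer.params[name].astype(self.dtype)
            if isinstance(layer, BatchNorm):
                layer.running_mean = layer.running_mean.astype(self.dtype)
                layer.running_var = layer.running_var.astype(self.dtype)
        self.output_shape = shape
        self.built = True

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        lr: float = 0.001,
        seed: int = 0,
    ) -> "Sequential":
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if not self.built:
            self.build(X.shape[1:], seed=seed)
        if self.output_shape != (n_classes,):
            raise ValueError(
                f"model outputs {self.output_shape}, data has {n_classes} classes"
            )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = drop_rng
        onehot = np.eye(n_classes, dtype=self.dtype)[y_idx]
        opt = _Adam(lr=lr)
        n = X.shape[0]
        self.history_ = []
        for _ in range(epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                xb, yb = X[idx], onehot[idx]
                logits = self.forward(xb, training=True)
                p = _softmax(logits)
                losses.append(
                    float(-np.mean(np.log(np.clip((p * yb).sum(axis=1), 1e-12, None))))
                )
                self.backward((p - yb) / len(idx))
                opt.step(self.layers)
            self.history_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(np.asarray(X, dtype=self.dtype), training=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def layer_census(model: Sequential) -> dict[str, int]:
    """Count layers by class name (activation layers included)."""
    census: dict[str, int] = {}
    for layer in model.layers:
        name = type(layer).__name__
        census[name] = census.get(name, 0) + 1
    return census
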