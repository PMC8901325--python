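"""Minimal feed-forward / convolutional network engine.

Implements exactly the layer types the classification pipeline needs —
strided 2-D convolution, ReLU, 2x2 max pooling, flatten, dense — together
with softmax/sigmoid heads, cross-entropy losses and SGD/Adam optimisers.
Everything is plain numpy with explicit backpropagation, seeded
deterministic initialisation, and no hidden global state, so that two runs
with the same seed and data produce bit-identical weights.

Shapes follow the NCHW convention: images are ``(n, channels, height,
width)`` and tabular inputs are ``(n, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Network",
    "SGD",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid",
    "binary_cross_entropy",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold ``(n, c, h, w)`` into ``(n * oh * ow, c * k * k)`` patches."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


class Layer:
    """Base layer: parameter-free unless overridden."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def out_spatial(self, side: int) -> int:
        return side


class Conv2D(Layer):
    """k x k convolution with configurable stride and zero padding.

    He-normal initialisation from the supplied generator keeps runs
    reproducible.
    """

    def __init__(self, in_ch: int, out_ch: int, *, kernel_size: int = 3,
                 stride: int = 2, padding: int = 1, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel_size, stride, padding
        fan_in = in_ch * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        b = np.zeros(out_ch)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        w, b = self.params
        out = cols @ w.T + b
        n = x.shape[0]
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        w, _ = self.params
        self.grads[0][...] = g.T @ self._cols
        self.grads[1][...] = g.sum(axis=0)
        dcols = g @ w  # (n*oh*ow, c*k*k)
        return self._col2im(dcols)

    def _col2im(self, dcols: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k, stride, pad = self.k, self.stride, self.pad
        oh, ow = self._oh, self._ow
        dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        for i in range(k):
            for j in range(k):
                dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if pad:
            dx = dx[:, :, pad:-pad, pad:-pad]
        return dx

    def out_spatial(self, side: int) -> int:
        return (side + 2 * self.pad - self.k) // self.stride + 1


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; the input side must be >= the pool size."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        oh, ow = h // s, w // s
        if oh == 0 or ow == 0:
            raise ValueError(f"max-pool input {h}x{w} smaller than pool size {s}")
        x = x[:, :, : oh * s, : ow * s]
        self._x_shape = x.shape
        windows = x.reshape(n, c, oh, s, ow, s)
        self._windows = windows
        out = windows.max(axis=(3, 5))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        s = self.size
        mask = self._windows == self._out[:, :, :, None, :, None]
        # Split gradient equally among tied maxima so backward stays exact.
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx = mask * (grad[:, :, :, None, :, None] / counts)
        return dx.reshape(n, c, h, w)

    def out_spatial(self, side: int) -> int:
        return side // self.size


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        b = np.zeros(out_dim)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_dim:
            raise ValueError(
                f"dense layer expected {self.in_dim} input features, got {x.shape[1]}"
            )
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ w.T


class Network:
    """An ordered stack of layers with a shared parameter list."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over integer labels; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def binary_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE on sigmoid(logits) for 0/1 labels; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = sigmoid(logits)
    eps = 1e-12
    loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean()
    return float(loss), (p - y) / n


class SGD:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3) -> None:
        self.params, self.grads, self.lr = params, grads, lr

    def step(self) -> None:
        for p, g in zip(self.params, self.grads):
            p -= self.lr * g


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads, self.lr = params, grads, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, params: list[np.ndarray], grads: list[np.ndarray],
                   lr: float):
    if name == "sgd":
        return SGD(params, grads, lr)
    if name == "adam":
        return Adam(params, grads, lr)
    raise ValueError(f"unknown optimizer {name!r}; expected 'sgd' or 'adam'")
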