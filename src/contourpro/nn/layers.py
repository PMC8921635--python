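"""Layers with forward/backward passes (NCHW, float32).

Each layer caches whatever its backward pass needs during forward, so an
instance participates in exactly one position of a network graph.  Same
padding is used for all convolutions (pad = k // 2), so stride-1 convs
preserve the spatial size and stride-2 convs halve even sizes exactly.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A learnable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c * k * k, oh * ow), dtype=F32)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            cols[:, (np.arange(c) * k * k + i * k + j), :] = patch.reshape(n, c, oh * ow)
    return cols


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    n, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=F32)
    for i in range(k):
        for j in range(k):
            patch = dcols[:, (np.arange(c) * k * k + i * k + j), :].reshape(n, c, oh, ow)
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += patch
    return dxp


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        p = self.k // 2
        oh = (h + 2 * p - self.k) // self.stride + 1
        ow = (w + 2 * p - self.k) // self.stride + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, self.k, self.stride, oh, ow)
        out = np.matmul(self.w.value[None], cols) + self.b.value[None, :, None]
        self._cache = (cols, xp.shape, (h, w), (oh, ow))
        return out.reshape(n, self.cout, oh, ow)

    def backward(self, dy):
        cols, xp_shape, (h, w), (oh, ow) = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.cout, oh * ow)
        self.w.grad += np.einsum("nol,nkl->ok", dyf, cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T[None], dyf)
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, oh, ow)
        p = self.k // 2
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Upsample2x(Layer):
    """Nearest-neighbour 2× spatial upsampling."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape, excluding batch

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value = np.asarray(a, dtype=F32)
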