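"""Minimal neural-network engine for 3D segmentation.

Layers store their forward caches and implement explicit reverse-mode
gradients; there is no autograd. Everything is float32 and batch-free
(one volume at a time); the training loop accumulates gradients across
a batch by summation. Determinism: given the same parameter values,
inputs and dropout RNG state, forward and backward are bit-reproducible
(single-threaded kernels, fixed summation order).
"""
from __future__ import annotations

import numpy as np

from ._kernels import conv3d_forward, conv3d_grad_input, conv3d_grad_weights


class Param:
    """A learnable array with its gradient accumulator and a trainable flag."""

    __slots__ = ("name", "data", "grad", "trainable")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.trainable = True

    @property
    def size(self) -> int:
        return self.data.size


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


def _pad1(x: np.ndarray) -> np.ndarray:
    """Zero-pad 1 voxel per spatial side (cheaper than np.pad for this case)."""
    c, d, h, w = x.shape
    xp = np.zeros((c, d + 2, h + 2, w + 2), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, 1:-1] = x
    return xp


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_cache(self) -> None:
        pass


class Conv3x3(Layer):
    """3x3x3 convolution, zero padding 1, shape-preserving.

    ``input_layer=True`` skips the input-gradient computation (the
    gradient w.r.t. the network input is never used).
    """

    def __init__(self, rng, cin: int, cout: int, name: str, input_layer: bool = False):
        self.cin, self.cout = cin, cout
        self.input_layer = input_layer
        self.w = Param(name + ".w", he_init(rng, (cout, cin, 3, 3, 3), cin * 27))
        self.b = Param(name + ".b", np.zeros(cout, np.float32))
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, cache: bool):
        xp = _pad1(np.ascontiguousarray(x, dtype=np.float32))
        if cache:
            self._xp = xp
        return conv3d_forward(xp, self.w.data, self.b.data)

    def backward(self, gy):
        gy = np.ascontiguousarray(gy, np.float32)
        if self.w.trainable:
            dw, db = conv3d_grad_weights(self._xp, gy)
            self.w.grad += dw
            self.b.grad += db
        gx = None if self.input_layer else conv3d_grad_input(gy, self.w.data)
        self._xp = None
        return gx

    def zero_cache(self):
        self._xp = None


class Conv1x1(Layer):
    """Pointwise convolution (channel mixing)."""

    def __init__(self, rng, cin: int, cout: int, name: str):
        self.cin, self.cout = cin, cout
        self.w = Param(name + ".w", he_init(rng, (cout, cin), cin))
        self.b = Param(name + ".b", np.zeros(cout, np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, cache: bool):
        sp = x.shape[1:]
        x2 = x.reshape(self.cin, -1)
        if cache:
            self._x = x2
        y = self.w.data @ x2 + self.b.data[:, None]
        return y.reshape(self.cout, *sp)

    def backward(self, gy):
        sp = gy.shape[1:]
        g2 = gy.reshape(self.cout, -1).astype(np.float32, copy=False)
        if self.w.trainable:
            self.w.grad += g2 @ self._x.T
            self.b.grad += g2.sum(1)
        gx = self.w.data.T @ g2
        self._x = None
        return gx.reshape(self.cin, *sp)

    def zero_cache(self):
        self._x = None


class DownConv(Layer):
    """Strided 2x2x2 convolution halving each spatial dimension."""

    def __init__(self, rng, cin: int, cout: int, name: str):
        self.cin, self.cout = cin, cout
        self.w = Param(name + ".w", he_init(rng, (cout, cin * 8), cin * 8))
        self.b = Param(name + ".b", np.zeros(cout, np.float32))
        self._col = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _to_col(x):
        c, d, h, w = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        col = xr.transpose(0, 2, 4, 6, 1, 3, 5).reshape(c * 8, -1)
        return np.ascontiguousarray(col)

    def forward(self, x, cache: bool):
        c, d, h, w = x.shape
        col = self._to_col(x)
        if cache:
            self._col = col
        y = self.w.data @ col + self.b.data[:, None]
        return y.reshape(self.cout, d // 2, h // 2, w // 2)

    def backward(self, gy):
        _, d2, h2, w2 = gy.shape
        g2 = gy.reshape(self.cout, -1).astype(np.float32, copy=False)
        if self.w.trainable:
            self.w.grad += g2 @ self._col.T
            self.b.grad += g2.sum(1)
        dcol = self.w.data.T @ g2
        dcol = dcol.reshape(self.cin, 2, 2, 2, d2, h2, w2)
        gx = dcol.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.cin, d2 * 2, h2 * 2, w2 * 2)
        self._col = None
        return np.ascontiguousarray(gx)

    def zero_cache(self):
        self._col = None


class UpConv(Layer):
    """Transposed 2x2x2 convolution doubling each spatial dimension."""

    def __init__(self, rng, cin: int, cout: int, name: str):
        self.cin, self.cout = cin, cout
        self.w = Param(name + ".w", he_init(rng, (cout * 8, cin), cin))
        self.b = Param(name + ".b", np.zeros(cout, np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, cache: bool):
        c, d, h, w = x.shape
        x2 = x.reshape(c, -1)
        if cache:
            self._x = x2
        y8 = self.w.data @ x2  # (cout*8, V)
        y = y8.reshape(self.cout, 2, 2, 2, d, h, w)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.cout, d * 2, h * 2, w * 2)
        return np.ascontiguousarray(y) + self.b.data[:, None, None, None]

    def backward(self, gy):
        _, d2, h2, w2 = gy.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        gr = gy.reshape(self.cout, d, 2, h, 2, w, 2)
        g8 = np.ascontiguousarray(gr.transpose(0, 2, 4, 6, 1, 3, 5)).reshape(self.cout * 8, -1)
        if self.w.trainable:
            self.w.grad += g8 @ self._x.T
            self.b.grad += gy.reshape(self.cout, -1).sum(1).astype(np.float32)
        gx = self.w.data.T @ g8
        self._x = None
        return gx.reshape(self.cin, d, h, w)

    def zero_cache(self):
        self._x = None


class ReLU(Layer):
    """Rectifier applied in place (its input is always a fresh conv output)."""

    def __init__(self):
        self._out = None

    def forward(self, x, cache: bool):
        y = np.maximum(x, 0.0, out=x)
        if cache:
            self._out = y
        return y

    def backward(self, gy):
        gy *= self._out > 0
        self._out = None
        return gy

    def zero_cache(self):
        self._out = None


class Dropout(Layer):
    """Inverted dropout; identity when ``rate == 0`` or in inference mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, cache: bool, rng: np.random.Generator | None = None):
        if rng is None or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / np.float32(keep)
        if cache:
            self._mask = mask
        return x * mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        gx = gy * self._mask
        self._mask = None
        return gx

    def zero_cache(self):
        self._mask = None


_PROB_FLOOR = np.float32(1e-12)  # keeps probabilities out of the denormal
                                 # range, whose hardware penalty dominates
                                 # saturated-network training time


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, _PROB_FLOOR, 1.0 - _PROB_FLOOR, out=out)


class Optimizer:
    """Per-parameter adaptive step on trainable parameters only."""

    def __init__(self, params: list[Param], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = np.float32(lr)
        self.state = {p.name: np.zeros_like(p.data) for p in params}

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            if p.trainable:
                self._update(p, self.state[p.name])

    def _update(self, p: Param, s: np.ndarray):  # pragma: no cover
        raise NotImplementedError


class AdaGrad(Optimizer):
    """AdaGrad with the Keras conventions: accumulator initialized at 0.1
    (not 0, which would make the first steps ~lr*sign(g) and wreck an
    already-trained model) and epsilon 1e-7."""

    eps = np.float32(1e-7)
    initial_accumulator = np.float32(0.1)

    def __init__(self, params, lr):
        super().__init__(params, lr)
        for s in self.state.values():
            s[...] = self.initial_accumulator

    def _update(self, p, s):
        s += p.grad * p.grad
        p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class RMSprop(Optimizer):
    eps = np.float32(1e-7)
    rho = np.float32(0.9)

    def _update(self, p, s):
        s *= self.rho
        s += (1.0 - self.rho) * p.grad * p.grad
        p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


OPTIMIZERS = {"adagrad": AdaGrad, "rmsprop": RMSprop}


def make_optimizer(name: str, params: list[Param], lr: float) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}") from None
    return cls(params, lr)
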