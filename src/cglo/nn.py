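"""Minimal feed-forward layers with hand-written gradients, and Adam.

Everything is dense numpy.  Each layer caches what its backward pass
needs during ``forward`` and accumulates parameter gradients into ``Param.grad``
during ``backward``; ``backward`` returns the gradient with respect to the
layer input so layers chain.  This is deliberately small: just the pieces the
convolutional generator and the U-Net prior need (transposed/strided
convolutions, batch normalization, bilinear resizing, the usual activations).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Sequential", "Linear", "Reshape", "Conv2d",
    "ConvTranspose2d", "BatchNorm2d", "ReLU", "LeakyReLU", "Sigmoid",
    "BilinearResize", "Concat", "Adam", "DTYPE", "set_default_dtype",
]

# float32 is the working precision: BLAS throughput roughly doubles and the
# optimizations here never need more.  Gradient-verification tests switch to
# float64 for tight finite-difference tolerances.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used by newly created parameters and buffers."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_std: float = 0.02):
        self.W = Param(rng.normal(0.0, w_std, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gy):
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(self._in_shape)


# -- convolution plumbing ----------------------------------------------------
# im2col/col2im with BLAS matmuls.  The same two primitives serve Conv2d
# (forward = im2col + matmul) and ConvTranspose2d (forward = matmul + col2im);
# each is the exact adjoint of the other.

def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """``x (B,C,H,W)`` -> contiguous ``(C*k*k, B*Ho*Wo)`` patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)
                                ).reshape(c * k * k, b * ho * wo)
    return cols, (b, ho, wo)


def _col2im(cols: np.ndarray, out_shape: tuple[int, int, int, int], k: int,
            stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto an image."""
    b, c, h, w = out_shape
    patches = cols.reshape(c, k, k, b, ho, wo)
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride,
                j:j + stride * wo:stride] += patches[:, i, j].transpose(
                    1, 0, 2, 3)
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def _to_mat(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (C, B*H*W)"""
    return np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(
        x.shape[1], -1)


def _from_mat(m: np.ndarray, b: int, h: int, w: int) -> np.ndarray:
    return m.reshape(m.shape[0], b, h, w).transpose(1, 0, 2, 3)


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, w_std: float = 0.02):
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.k = k
        self.W = Param(rng.normal(0.0, w_std, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        cols, (b, ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        return _from_mat(wmat @ cols, b, ho, wo) \
            + self.b.value[None, :, None, None]

    def backward(self, gy):
        b, co, ho, wo = gy.shape
        gym = _to_mat(gy)
        self.W.grad += (gym @ self._cols.T).reshape(self.W.value.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        wmat = self.W.value.reshape(co, -1)
        return _col2im(wmat.T @ gym, self._x_shape, self.k, self.stride,
                       self.pad, ho, wo)


class ConvTranspose2d(Layer):
    """Transposed convolution, kernel 4, stride 2, padding 1 by default —
    exactly doubles the spatial size (the DCGAN upsampling block)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1, w_std: float = 0.02):
        self.k, self.stride, self.pad = k, stride, pad
        # stored as the weight of the adjoint convolution: (c_in, c_out, k, k)
        self.W = Param(rng.normal(0.0, w_std, size=(c_in, c_out, k, k)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, train=True):
        b, ci, h, w = x.shape
        self._x_mat = _to_mat(x)
        hh, ww = self.out_size(h), self.out_size(w)
        wmat = self.W.value.reshape(ci, -1)
        y = _col2im(wmat.T @ self._x_mat,
                    (b, self.W.value.shape[1], hh, ww),
                    self.k, self.stride, self.pad, h, w)
        return y + self.b.value[None, :, None, None]

    def backward(self, gy):
        ci = self.W.value.shape[0]
        cols, (b, ho, wo) = _im2col(gy, self.k, self.stride, self.pad)
        self.W.grad += (self._x_mat @ cols.T).reshape(self.W.value.shape)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        wmat = self.W.value.reshape(ci, -1)
        return _from_mat(wmat @ cols, b, ho, wo)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, train)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, gy):
        xhat, std, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = gy * self.gamma.value[None, :, None, None]
        if not train:
            return g / std[None, :, None, None]
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        sum_g = g.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (g - sum_g / m - xhat * sum_gx / m) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-center convention)."""
    A = np.zeros((n_out, n_in))
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    A[np.arange(n_out), lo] += 1 - frac
    A[np.arange(n_out), hi] += frac
    return A.astype(DTYPE)


class BilinearResize(Layer):
    """Exact linear resize ``(H,W) -> (h_out, w_out)``; its backward pass is
    the true adjoint of the interpolation."""

    def __init__(self, h_out: int, w_out: int):
        self.h_out, self.w_out = h_out, w_out
        self._A = None
        self._B = None

    def forward(self, x, train=True):
        if self._A is None or self._A.shape[1] != x.shape[2] \
                or self._B.shape[1] != x.shape[3]:
            self._A = _resize_matrix(self.h_out, x.shape[2])
            self._B = _resize_matrix(self.w_out, x.shape[3])
        return np.matmul(np.matmul(self._A, x), self._B.T)

    def backward(self, gy):
        return np.matmul(np.matmul(self._A.T, gy), self._B)


class Concat(Layer):
    """Channel concatenation of two tensors (U-Net skip joins)."""

    def forward2(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        self._split = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, gy):
        return gy[:, :self._split], gy[:, self._split:]


class Adam:
    """Adam with parameter groups (distinct learning rates per group)."""

    def __init__(self, groups: list[tuple[list[Param], float]],
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {
            id(p): (np.zeros_like(p.value), np.zeros_like(p.value))
            for params, _ in groups for p in params
        }

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.zero_grad()

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for params, lr in self.groups:
            for p in params:
                m, v = self.state[id(p)]
                m += (1.0 - self.b1) * (p.grad - m)
                v += (1.0 - self.b2) * (p.grad ** 2 - v)
                p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class AdamRows:
    """Adam over rows of one matrix, updating only the rows touched at each
    step (used for per-image latent codes drawn in minibatches)."""

    def __init__(self, values: np.ndarray, lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.values = values
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = np.zeros_like(values)
        self.v = np.zeros_like(values)
        self.t = np.zeros(values.shape[0], dtype=np.int64)

    def step_rows(self, idx: np.ndarray, grad_rows: np.ndarray) -> None:
        self.t[idx] += 1
        t = self.t[idx][:, None].astype(np.float64)
        self.m[idx] += (1.0 - self.b1) * (grad_rows - self.m[idx])
        self.v[idx] += (1.0 - self.b2) * (grad_rows ** 2 - self.v[idx])
        mhat = self.m[idx] / (1.0 - self.b1 ** t)
        vhat = self.v[idx] / (1.0 - self.b2 ** t)
        self.values[idx] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
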