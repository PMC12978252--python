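"""Minimal reverse-mode neural-network layers on NumPy.

Implements exactly the operations the stability model needs — dense and
1-D convolutional layers (with dilation), batch normalisation, leaky-ReLU,
max pooling, dropout — each exposing an explicit ``forward``/``backward``
pair so that gradients with respect to *inputs* (needed for saliency) fall
out of the same code path as gradients with respect to parameters.

All arrays are float64; sequence tensors are laid out ``(N, C, L)``.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1d",
    "LeakyReLU",
    "BatchNorm1d",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
    "clip_global_norm",
    "global_grad_norm",
]


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless it declares params()."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense") -> None:
        self.W = Param(_he_init(rng, (n_in, n_out), n_in), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding and optional dilation.

    Input ``(N, C_in, L)`` → output ``(N, C_out, L)``.  The kernel is applied
    as a sum of ``k`` shifted matrix products, which keeps the implementation
    close to the definition and fast enough at the model sizes used here.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        name: str = "conv",
    ) -> None:
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        fan_in = c_in * kernel
        self.W = Param(_he_init(rng, (c_out, c_in, kernel), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._xcol: np.ndarray | None = None
        self._shape: tuple[int, int, int] = (0, 0, 0)
        self._pads: tuple[int, int] = (0, 0)

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, L = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, d = self.kernel, self.dilation
        span = d * (k - 1)
        left = span // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (left, span - left)))
        # im2col: (n, L, c*k) so the whole convolution is one GEMM
        taps = np.lib.stride_tricks.sliding_window_view(xpad, span + 1, axis=2)[..., ::d]
        xcol = np.ascontiguousarray(taps.transpose(0, 2, 1, 3)).reshape(n * L, c * k)
        self._xcol, self._shape, self._pads = xcol, (n, c, L), (left, span - left)
        Wmat = self.W.value.reshape(self.c_out, c * k)
        out = (xcol @ Wmat.T).reshape(n, L, self.c_out).transpose(0, 2, 1)
        return out + self.b.value[None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._xcol is not None
        n, c, L = self._shape
        k, d = self.kernel, self.dilation
        g2 = np.ascontiguousarray(grad_out.transpose(0, 2, 1)).reshape(n * L, self.c_out)
        self.W.grad += (g2.T @ self._xcol).reshape(self.c_out, c, k)
        self.b.grad += grad_out.sum(axis=(0, 2))
        dxcol = (g2 @ self.W.value.reshape(self.c_out, c * k)).reshape(n, L, c, k).transpose(0, 2, 1, 3)
        left, right = self._pads
        gxpad = np.zeros((n, c, L + left + right), dtype=grad_out.dtype)
        for i in range(k):
            gxpad[:, :, i * d : i * d + L] += dxcol[:, :, :, i]
        return gxpad[:, :, left : left + L]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return np.where(self._mask, grad_out, self.alpha * grad_out)


class BatchNorm1d(Layer):
    """Per-channel batch normalisation for (N, C, L) tensors.

    Training uses batch statistics over (N, L); evaluation uses running
    exponential-moving-average statistics, so eval-mode outputs are
    deterministic functions of the input.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2))
        self.beta.grad += grad_out.sum(axis=(0, 2))
        g = grad_out * self.gamma.value[None, :, None]
        if not train:
            return g * inv[None, :, None]
        m = shape[0] * shape[2]
        # standard batchnorm backward through batch statistics
        gsum = g.sum(axis=(0, 2))[None, :, None]
        gx = (g - gsum / m - xhat * (g * xhat).sum(axis=(0, 2))[None, :, None] / m) * inv[None, :, None]
        return gx


class MaxPool1d(Layer):
    """Non-overlapping max pooling along L; trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, L = x.shape
        lo = L // self.pool
        xr = x[:, :, : lo * self.pool].reshape(n, c, lo, self.pool)
        idx = xr.argmax(axis=3)
        self._cache = (idx, x.shape, lo)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        idx, shape, lo = self._cache
        n, c, L = shape
        gx = np.zeros((n, c, lo, self.pool), dtype=grad_out.dtype)
        np.put_along_axis(gx, idx[..., None], grad_out[..., None], axis=3)
        out = np.zeros(shape, dtype=grad_out.dtype)
        out[:, :, : lo * self.pool] = gx.reshape(n, c, lo * self.pool)
        return out


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        return grad_out.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


def global_grad_norm(params: list[Param]) -> float:
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad**2))
    return float(np.sqrt(total))


def clip_global_norm(params: list[Param], max_norm: float) -> float:
    """Scale gradients in place so the global L2 norm is <= max_norm.

    Returns the pre-clip norm.
    """
    norm = global_grad_norm(params)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def snapshot_params(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def restore_params(params: list[Param], snap: list[np.ndarray]) -> None:
    for p, v in zip(params, snap):
        p.value[...] = v


def clone_module(module):
    """Deep copy of a layer tree including running statistics."""
    return copy.deepcopy(module)
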