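"""Minimal 1-D convolutional network core on numpy.

Implements exactly the layers the encoder/decoder need — valid (no-padding)
strided 1-D convolution, ReLU, max/average pooling, fully connected layers —
with hand-derived backward passes and an Adam optimizer.  Array layout is
(batch, channels, length) throughout.  Everything is deterministic given the
seeded ``numpy.random.Generator`` used for initialization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def conv_output_length(n: int, kernel: int, stride: int) -> int:
    """Valid-convolution output length ⌊(n−kernel)/stride⌋ + 1 (also pooling)."""
    if n < kernel:
        raise ValueError(f"input length {n} shorter than kernel {kernel}")
    return (n - kernel) // stride + 1


def _windows(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Strided view (N, C, L_out, kernel) over the length axis; no copy."""
    n, c, t = x.shape
    l_out = conv_output_length(t, kernel, stride)
    s0, s1, s2 = x.strides
    return as_strided(x, shape=(n, c, l_out, kernel), strides=(s0, s1, s2 * stride, s2))


def fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d:
    """Valid strided 1-D convolution with bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.weight = Param(fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in))
        self.bias = Param(fan_in_uniform(rng, (out_channels,), fan_in))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = _windows(x, self.kernel, self.stride)  # (N, C, L, k)
        y = np.tensordot(win, self.weight.value, axes=([1, 3], [1, 2]))  # (N, L, O)
        return np.ascontiguousarray(y.transpose(0, 2, 1)) + self.bias.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        win = _windows(x, self.kernel, self.stride)
        # dW[o,c,k] = sum_{n,l} dy[n,o,l] win[n,c,l,k]
        self.weight.grad += np.tensordot(dy, win, axes=([0, 2], [0, 2]))
        self.bias.grad += dy.sum(axis=(0, 2))
        dx = np.zeros_like(x)
        l_out = dy.shape[2]
        for k in range(self.kernel):
            # (N, O, L) x (O, C) -> (N, C, L) scattered at positions l*stride+k
            contrib = np.einsum("nol,oc->ncl", dy, self.weight.value[:, :, k])
            dx[:, :, k : k + l_out * self.stride : self.stride] += contrib
        return dx

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def parameters(self) -> list[Param]:
        return []


class Pool1d:
    """Max (default) or average pooling over the length axis."""

    def __init__(self, window: int, stride: int, mode: str = "max"):
        if mode not in ("max", "avg"):
            raise ValueError("pooling mode must be 'max' or 'avg'")
        self.window = window
        self.stride = stride
        self.mode = mode
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = _windows(x, self.window, self.stride)
        if self.mode == "avg":
            self._cache = (x.shape,)
            return win.mean(axis=3)
        idx = win.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        l_out = dy.shape[2]
        if self.mode == "avg":
            (shape,) = self._cache
            dx = np.zeros(shape)
            for k in range(self.window):
                dx[:, :, k : k + l_out * self.stride : self.stride] += dy / self.window
            return dx
        shape, idx = self._cache
        dx = np.zeros(shape)
        n, c = shape[0], shape[1]
        ni, ci, li = np.ogrid[:n, :c, :l_out]
        np.add.at(dx, (ni, ci, li * self.stride + idx), dy)
        return dx

    def parameters(self) -> list[Param]:
        return []


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(fan_in_uniform(rng, (out_features, in_features), in_features))
        self.bias = Param(fan_in_uniform(rng, (out_features,), in_features))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class Adam:
    """Adaptive-moment gradient optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
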