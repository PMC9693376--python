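"""Small numpy neural-network engine used by the hybrid model.

Implements exactly the layer set the hybrid architecture needs —
embedding lookup, 1-D convolution (valid/same padding), ReLU, inverted
dropout, global max pooling, dense layers — with reverse-mode gradients
and an Adam optimiser.  Everything is float32 and driven by a single
``numpy.random.Generator``, so training is bit-reproducible given a
seed regardless of thread count (all heavy work is BLAS matmuls).

L2 penalties follow the Keras convention: a kernel with factor
``l2`` adds ``l2 * sum(W**2)`` to the loss, i.e. gradient ``2*l2*W``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter dict ``p``, gradient dict ``g``."""

    l2 = 0.0
    l2_keys: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.p: dict[str, np.ndarray] = {}
        self.g: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError

    def reg_loss(self) -> float:
        return self.l2 * sum(float(np.sum(self.p[k] ** 2)) for k in self.l2_keys)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(np.float32)


class Embedding(Layer):
    """Token-index lookup table; row 0 is the padding token."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.p["W"] = rng.uniform(-0.05, 0.05, (vocab_size, dim)).astype(np.float32)

    def forward(self, x, train=False):
        self._idx = x
        return self.p["W"][x]

    def backward(self, dy):
        dW = np.zeros_like(self.p["W"])
        dim = dW.shape[1]
        np.add.at(dW, self._idx.reshape(-1), dy.reshape(-1, dim))
        self.g["W"] = dW
        return None


class Conv1D(Layer):
    """1-D convolution over (K, L, C) inputs via im2col matmul."""

    l2_keys = ("W",)

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 padding: str, l2: float, rng: np.random.Generator):
        super().__init__()
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.kernel, self.padding, self.l2 = kernel, padding, l2
        self.in_channels = in_channels
        self.p["W"] = _glorot(rng, kernel * in_channels, filters,
                              (kernel * in_channels, filters))
        self.p["b"] = np.zeros(filters, dtype=np.float32)

    def _pad(self, x):
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            right = self.kernel - 1 - left
            return np.pad(x, ((0, 0), (left, right), (0, 0))), left
        return x, 0

    def forward(self, x, train=False):
        K, L, C = x.shape
        xp, self._left = self._pad(x)
        self._in_len = L
        if xp.shape[1] < self.kernel:  # input shorter than the kernel
            raise ValueError(
                f"input length {L} too short for kernel {self.kernel} with "
                f"{self.padding!r} padding"
            )
        win = sliding_window_view(xp, self.kernel, axis=1)  # (K, Lo, C, k)
        patches = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            K, -1, self.kernel * C
        )
        self._patches = patches
        return patches @ self.p["W"] + self.p["b"]

    def backward(self, dy):
        K, Lo, F = dy.shape
        kC = self.p["W"].shape[0]
        self.g["W"] = (
            self._patches.reshape(-1, kC).T @ dy.reshape(-1, F)
            + 2.0 * self.l2 * self.p["W"]
        )
        self.g["b"] = dy.sum(axis=(0, 1))
        dpatch = (dy @ self.p["W"].T).reshape(K, Lo, self.kernel, self.in_channels)
        pad_len = self._in_len + (self.kernel - 1 if self.padding == "same" else 0)
        dxp = np.zeros((K, pad_len, self.in_channels), dtype=np.float32)
        for j in range(self.kernel):
            dxp[:, j:j + Lo, :] += dpatch[:, :, j, :]
        return dxp[:, self._left:self._left + self._in_len, :]


class Dense(Layer):
    l2_keys = ("W",)

    def __init__(self, in_dim: int, out_dim: int, l2: float,
                 rng: np.random.Generator):
        super().__init__()
        self.l2 = l2
        self.p["W"] = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.p["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, dy):
        self.g["W"] = self._x.T @ dy + 2.0 * self.l2 * self.p["W"]
        self.g["b"] = dy.sum(axis=0)
        return dy @ self.p["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GlobalMaxPool(Layer):
    """(K, L, C) -> (K, C) per-filter maximum over positions."""

    def forward(self, x, train=False):
        self._shape = x.shape
        self._arg = x.argmax(axis=1)  # (K, C)
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=np.float32)
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with Keras-style defaults (eps 1e-7)."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.p[k]) for layer, k in params]
        self.v = [np.zeros_like(layer.p[k]) for layer, k in params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for i, (layer, key) in enumerate(self.params):
            g = layer.g[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.p[key] -= (lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)).astype(
                np.float32
            )


def collect_params(layers: list[Layer]) -> list[tuple[Layer, str]]:
    return [(layer, key) for layer in layers for key in layer.p]
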