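"""Minimal CPU neural-network engine (numpy).

Provides exactly the pieces the toolkit needs for desk-scale experiments:
2-D convolution (im2col), batch normalization with separately addressable
inference statistics, ReLU, global average pooling, a linear head, and
reverse-mode gradients through all of them.  Everything is float32 and
deterministic given a seeded ``numpy.random.Generator``.

The engine is deliberately small: plain layer objects with ``forward`` /
``backward`` methods and explicit parameter dictionaries, so that structured
channel pruning can slice weight tensors directly and attention methods can
read activations and gradients at any layer boundary.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "GlobalAvgPool", "Linear"]


def _sliding(x: np.ndarray, K: int, stride: int) -> np.ndarray:
    # x: (N, C, Hp, Wp) -> (N, C, Ho, Wo, K, K)
    w = np.lib.stride_tricks.sliding_window_view(x, (K, K), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


class Conv2d:
    """Same-family conv layer; kernel K, stride s, zero padding ``pad``."""

    def __init__(self, cin: int, cout: int, K: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None):
        self.cin, self.cout, self.K, self.stride = cin, cout, K, stride
        self.pad = (K // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * K * K
        # He-normal init, the standard choice before ReLU
        self.W = (rng.standard_normal((cout, cin, K, K)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cache = None

    def params(self):
        out = {"W": self.W}
        if self.b is not None:
            out["b"] = self.b
        return out

    def grads(self):
        out = {"W": self.dW}
        if self.b is not None:
            out["b"] = self.db
        return out

    def out_shape(self, H: int, W: int) -> tuple[int, int]:
        Ho = (H + 2 * self.pad - self.K) // self.stride + 1
        Wo = (W + 2 * self.pad - self.K) // self.stride + 1
        return Ho, Wo

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        assert C == self.cin, (C, self.cin)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = _sliding(xp, self.K, self.stride)           # N,C,Ho,Wo,K,K
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * self.K * self.K)
        out = cols @ self.W.reshape(self.cout, -1).T
        if self.b is not None:
            out += self.b
        self._cache = (cols, (N, C, H, W), (Ho, Wo)) if train else None
        return out.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (N, C, H, W), (Ho, Wo) = self._cache
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.cout)
        self.dW = (dy_mat.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.db = dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.W.reshape(self.cout, -1)).reshape(
            N, Ho, Wo, C, self.K, self.K)
        Hp, Wp = H + 2 * self.pad, W + 2 * self.pad
        dxp = np.zeros((N, C, Hp, Wp), dtype=dy.dtype)
        s = self.stride
        for ki in range(self.K):
            for kj in range(self.K):
                dxp[:, :, ki:ki + s * Ho:s, kj:kj + s * Wo:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class BatchNorm2d:
    """Channel-wise batch normalization.

    Training mode normalizes with the current mini-batch statistics and keeps
    an exponential running estimate for inference; the running statistics are
    plain attributes so they can be replaced wholesale (adaptive
    recalibration after pruning).
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[:, None, None]
        dx = (inv[:, None, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        return dx.astype(dy.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return {}

    def grads(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return {}

    def grads(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W), self._shape).astype(dy.dtype)


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(cin)
        self.W = rng.uniform(-bound, bound, (cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, (g / n).astype(np.float32)
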