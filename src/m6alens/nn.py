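"""Minimal numpy neural-network layers for 1-D sequence models.

Implements exactly what the per-nucleotide classifier needs: dilated 1-D
convolutions with 'same' zero padding, batch normalisation, ReLU,
softmax/cross-entropy with a per-position mask, and Adam.  Everything is
float64 and single-threaded-deterministic; gradients are verified against
finite differences in the test suite.

Array layout is (N, L, C): batch, sequence position, channels.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    """Dilated 1-D convolution, 'same' zero padding, odd window only."""

    def __init__(self, c_in: int, c_out: int, w: int = 1, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if w % 2 != 1:
            raise ValueError("window size must be odd")
        self.w, self.ar = w, dilation
        rng = rng or np.random.default_rng(0)
        # He-normal initialisation for the ReLU pipeline
        std = np.sqrt(2.0 / (w * c_in))
        self.W = rng.normal(0.0, std, size=(w, c_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def margin(self) -> int:
        """Receptive-field half-width contributed by this layer (nt)."""
        return (self.w - 1) // 2 * self.ar

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        pad = self.margin
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        self._xp_shape = xp.shape
        self._xp = xp
        y = np.broadcast_to(self.b, (n, L, self.b.shape[0])).copy()
        for j in range(self.w):
            off = j * self.ar
            y += xp[:, off:off + L, :] @ self.W[j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, L, _ = dy.shape
        pad = self.margin
        dxp = np.zeros(self._xp_shape)
        self.db[...] = dy.sum(axis=(0, 1))
        for j in range(self.w):
            off = j * self.ar
            xs = self._xp[:, off:off + L, :]
            self.dW[j] = np.einsum("nli,nlo->io", xs, dy)
            dxp[:, off:off + L, :] += dy @ self.W[j].T
        self._xp = None
        return dxp[:, pad:pad + L, :] if pad else dxp

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over the (N, L) axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, m = self._cache
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dy.sum(axis=(0, 1))
        if not train:
            return dy * self.gamma * inv
        dxhat = dy * self.gamma
        # standard batchnorm backward over the pooled (N*L) sample axis
        return (inv / m) * (m * dxhat
                            - dxhat.sum(axis=(0, 1))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1)))

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return x * self._pos

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def masked_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                         mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over mask==1 positions.

    labels: (N, L) int class ids; returns (loss, dLoss/dlogits).
    """
    p = softmax(logits)
    n, L, k = logits.shape
    m = mask.astype(float)
    total = m.sum()
    if total == 0:
        return 0.0, np.zeros_like(logits)
    idx = (np.arange(n)[:, None], np.arange(L)[None, :], labels)
    loss = -(np.log(np.clip(p[idx], 1e-12, None)) * m).sum() / total
    grad = p.copy()
    grad[idx] -= 1.0
    grad *= (m / total)[..., None]
    return float(loss), grad


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
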