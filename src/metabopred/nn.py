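"""Minimal dense neural-network machinery: MLP, Adam, masked softmax.

Everything is plain NumPy with explicit backprop. The networks used in this
package are small (a shared per-candidate scoring head and a fingerprint
autoencoder), so a hand-rolled implementation keeps the dependency surface
tiny and the arithmetic fully deterministic for a given seed and BLAS.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float64)


class MLP:
    """Fully-connected network, ReLU hidden layers, linear output."""

    def __init__(self, dims: Sequence[int], seed: int = 0, zero_init: bool = False):
        if len(dims) < 2:
            raise ValueError("need at least input and output dims")
        self.dims = list(dims)
        rng = np.random.default_rng(seed)
        self.W = []
        self.b = []
        for i in range(len(dims) - 1):
            if zero_init:
                self.W.append(np.zeros((dims[i], dims[i + 1])))
            else:
                self.W.append(he_init(rng, dims[i], dims[i + 1]))
            self.b.append(np.zeros(dims[i + 1]))

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> tuple[np.ndarray, list]:
        """Returns (output, cache). Inverted dropout on hidden activations."""
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < last:
                a = np.maximum(z, 0.0)
                if dropout > 0.0 and rng is not None:
                    keep = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                    a = a * keep
                else:
                    keep = None
                cache.append((h, z, keep))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def backward(self, cache: list, dout: np.ndarray, return_dinput: bool = False):
        """Gradients [(dW, db), ...] matching self.W/self.b order.

        With ``return_dinput`` also returns the gradient w.r.t. the network
        input (needed when networks are chained, e.g. autoencoders).
        """
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.W)  # type: ignore
        d = dout
        for i in range(len(self.W) - 1, -1, -1):
            h, _, _ = cache[i]
            grads[i] = (h.T @ d, d.sum(axis=0))
            if i > 0:
                dh = d @ self.W[i].T  # grad wrt layer i-1 post-activation
                _, z_prev, keep_prev = cache[i - 1]
                d = dh * (z_prev > 0.0)
                if keep_prev is not None:
                    d = d * keep_prev
        if return_dinput:
            return grads, d @ self.W[0].T
        return grads

    def params(self):
        return list(zip(self.W, self.b))


class Adam:
    def __init__(self, shapes_like: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in shapes_like]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in shapes_like]

    def step(self, mlp: MLP, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for i, (dW, db) in enumerate(grads):
            mW, mb = self.m[i]
            vW, vb = self.v[i]
            mW += (1 - self.b1) * (dW - mW)
            mb += (1 - self.b1) * (db - mb)
            vW += (1 - self.b2) * (dW * dW - vW)
            vb += (1 - self.b2) * (db * db - vb)
            mlp.W[i] -= self.lr * (mW / c1) / (np.sqrt(vW / c2) + self.eps)
            mlp.b[i] -= self.lr * (mb / c1) / (np.sqrt(vb / c2) + self.eps)


def masked_softmax(scores: np.ndarray, mask: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax over unmasked entries; masked entries get probability exactly 0.

    ``mask`` is 1 for real entries, 0 for padding. Raises if a row is fully
    masked.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=axis).all():
        raise ValueError("all entries masked in at least one candidate set")
    s = np.where(mask, scores, -np.inf)
    s = s - np.max(s, axis=axis, keepdims=True)
    e = np.exp(s)
    e = np.where(mask, e, 0.0)
    return e / e.sum(axis=axis, keepdims=True)
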