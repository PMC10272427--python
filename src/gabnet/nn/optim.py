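"""Optimisers and the cross-entropy objective."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "softmax_cross_entropy", "softmax"]


class Adam:
    """Standard Adam with bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain (B, K) array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax(logits).

    The max-shift for numerical stability is treated as a constant, which
    leaves the gradient unchanged.
    """
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - log_norm
    b = logits.data.shape[0]
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(b), np.asarray(labels, dtype=int)] = 1.0
    return (logp * onehot).sum() * (-1.0 / b)
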