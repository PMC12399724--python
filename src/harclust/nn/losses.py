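"""Training losses: each returns (scalar loss, gradient w.r.t. input)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean categorical cross-entropy over integer class labels."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-300, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def mse(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements."""
    diff = pred - target
    return float((diff**2).mean()), 2.0 * diff / diff.size
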