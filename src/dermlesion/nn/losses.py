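"""Training losses: BCE + soft-Dice for segmentation, softmax CE for classification."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

_EPS = 1e-7


def binary_cross_entropy(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean BCE between probabilities `pred` and a binary array `target`."""
    t = np.asarray(target, dtype=np.float32)
    p = pred.clip(_EPS, 1.0 - _EPS)
    return -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()).mean()

def soft_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice; per-sample over all non-batch axes, then averaged."""
    t = np.asarray(target, dtype=np.float32)
    axes = tuple(range(1, pred.ndim))
    inter = (pred * Tensor(t)).sum(axis=axes)
    denom = pred.sum(axis=axes) + Tensor(t.sum(axis=axes))
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return 1.0 - dice.mean()


def bce_dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Equal-weight sum of BCE and soft-Dice, the segmentation objective."""
    return binary_cross_entropy(pred, target) + soft_dice_loss(pred, target)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax of `logits` (N, C)."""
    labels = np.asarray(labels)
    n, c = logits.shape
    onehot = np.zeros((n, c), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    # stabilise with a constant shift (no gradient path needed through a max)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    log_softmax = z - z.exp().sum(axis=1, keepdims=True).log()
    return -(Tensor(onehot) * log_softmax).sum() * (1.0 / n)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
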