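"""Training losses returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy for integer labels; gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)

_EPS = 1e-6


def bce_dice_loss(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Pixel-wise binary cross-entropy plus soft-Dice (equal weights).

    Standard combination for class-imbalanced binary segmentation; the
    Dice term is computed over the whole batch.
    """
    y = targets.astype(np.float32)
    p = sigmoid(logits)
    size = logits.size
    bce = float(
        -(y * np.log(p + 1e-9) + (1.0 - y) * np.log(1.0 - p + 1e-9)).mean()
    )
    dbce = (p - y) / size

    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + _EPS
    dice = 1.0 - (2.0 * inter + _EPS) / denom
    # d(dice)/dp, then chain through the sigmoid
    ddice_dp = -(2.0 * y * denom - (2.0 * inter + _EPS)) / denom**2
    ddice = ddice_dp * p * (1.0 - p)

    return bce + dice, (dbce + ddice).astype(np.float32)
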