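"""Cross-entropy / Dice loss family.

The binary forms operate on probability tensors; the combined multi-class
loss operates on raw logits.  All functions accept either numpy arrays or
autograd tensors and return autograd tensors, so they are usable both for
training and for direct scalar verification.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor

CE_EPS = 1e-7        # probability clamp for log stability
DICE_SMOOTH = 1e-5   # smoothing added to soft-Dice numerator and denominator


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the hybrid loss: total = lambda1*CE + lambda2*Dice."""

    lambda1: float = 0.4
    lambda2: float = 0.6

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be >= 0")


def ce_loss(probs, targets) -> Tensor:
    """Mean binary cross-entropy -(1/N) sum[y log p + (1-y) log(1-p)]."""
    probs = as_tensor(probs)
    targets = as_tensor(targets)
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    p = ag.clip(probs, CE_EPS, 1.0 - CE_EPS)
    y = targets
    ll = y * ag.log(p) + (1.0 - y) * ag.log(1.0 - p)
    return -1.0 * ll.mean()


def dice_loss(probs, targets) -> Tensor:
    """Soft Dice loss 1 - 2*sum(p*y)/(sum(p)+sum(y)), lightly smoothed."""
    probs = as_tensor(probs)
    targets = as_tensor(targets)
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    inter = (probs * targets).sum()
    denom = probs.sum() + targets.sum()
    return 1.0 - (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)


@dataclasses.dataclass
class CombinedLoss:
    total: Tensor
    ce: Tensor
    dice: Tensor
    weights: LossWeights


def combined_loss(logits, label_map, weights: LossWeights = LossWeights()) -> CombinedLoss:
    """Hybrid multi-class loss on (N,K+1,H,W) (or (K+1,H,W)) logits.

    CE is the multi-class negative log-likelihood of the true class; Dice is
    the soft Dice loss averaged over the K foreground classes.
    """
    logits = as_tensor(logits)
    if logits.ndim == 3:
        logits = ag.reshape(logits, (1,) + logits.shape)
        label_map = np.asarray(label_map)[None]
    labels = np.asarray(label_map)
    n, kp1, h, w = logits.shape
    if labels.shape != (n, h, w):
        raise ValueError(f"label shape {labels.shape} does not match logits {logits.shape}")
    if labels.min() < 0 or labels.max() >= kp1:
        raise ValueError(f"labels must lie in 0..{kp1 - 1}")

    probs = ag.softmax(logits, axis=1)
    onehot = np.zeros((n, kp1, h, w))
    np.put_along_axis(onehot, labels[:, None].astype(np.intp), 1.0, axis=1)

    p = ag.clip(probs, CE_EPS, 1.0 - CE_EPS)
    ce = -1.0 * (Tensor(onehot) * ag.log(p)).sum() * (1.0 / (n * h * w))

    dice_terms = [dice_loss(probs[:, k], onehot[:, k]) for k in range(1, kp1)]
    dice = dice_terms[0]
    for t in dice_terms[1:]:
        dice = dice + t
    dice = dice * (1.0 / len(dice_terms))

    total = weights.lambda1 * ce + weights.lambda2 * dice
    return CombinedLoss(total=total, ce=ce, dice=dice, weights=weights)
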