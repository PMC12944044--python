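"""Decoupled Feature Module (DFM).

Splits the deep encoder feature f into K parallel foreground branches and
one background branch, predicts one soft mask per branch through a joint
per-pixel softmax (so the K+1 masks are exactly complementary), and
supervises them with a dynamically weighted CE+Dice loss.

The dynamic weight of class k is

    beta_k = 1 - sigmoid(alpha * (p_k - mu)),

where p_k is the predicted pixel proportion of class k and mu the mean
proportion over the foreground classes.  Classes occupying fewer pixels
than average get beta_k > 1/2, which counteracts the tendency of large
structures to dominate the loss.  The weights are treated as constants
(detached), so the optimizer cannot shrink a predicted mask merely to
inflate its own weight.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .losses import ce_loss, dice_loss

DEFAULT_ALPHA = 5.0
DEFAULT_LAMBDA_BG = 0.3


@dataclasses.dataclass
class PriorMaskSet:
    """K soft foreground masks + 1 background mask, per-pixel complementary."""

    fg_masks: Tensor   # (N, K, H, W)
    bg_mask: Tensor    # (N, 1, H, W)
    logits: Tensor     # (N, K+1, H, W), channel order [fg_1..fg_K, bg]

    @property
    def num_fg_classes(self) -> int:
        return self.fg_masks.shape[1]

    @property
    def all_masks(self) -> Tensor:
        return ag.concat([self.fg_masks, self.bg_mask], axis=1)

    def resized(self, h: int, w: int) -> "PriorMaskSet":
        if (h, w) == self.fg_masks.shape[2:]:
            return self
        return PriorMaskSet(
            fg_masks=ag.resize_bilinear(self.fg_masks, h, w),
            bg_mask=ag.resize_bilinear(self.bg_mask, h, w),
            logits=ag.resize_bilinear(self.logits, h, w),
        )

    def detached(self) -> "PriorMaskSet":
        return PriorMaskSet(self.fg_masks.detach(), self.bg_mask.detach(),
                            self.logits.detach())


@dataclasses.dataclass
class DynamicWeightVector:
    beta: np.ndarray         # length K, each in (0, 1)
    alpha: float
    mu: float
    proportions: np.ndarray  # length K


@dataclasses.dataclass
class DFMLossBreakdown:
    per_class_losses: list   # K scalar tensors (L_k)
    bg_loss: Tensor
    weights: DynamicWeightVector
    total: Tensor
    lambda_bg: float


class DecoupledFeatureModule(nn.Module):
    """K+1 independent convolutional branches with 1-channel mask heads."""

    def __init__(self, rng, in_channels: int, num_fg_classes: int,
                 branch_channels: int | None = None):
        super().__init__()
        if num_fg_classes < 1:
            raise ValueError("num_fg_classes must be >= 1")
        self.num_fg_classes = num_fg_classes
        bc = branch_channels or max(in_channels // 4, 16)
        self.branches = [
            nn.Sequential(
                nn.conv_bn_relu(rng, in_channels, bc),
                nn.conv_bn_relu(rng, bc, bc),
            )
            for _ in range(num_fg_classes + 1)
        ]
        self.heads = [nn.Conv2d(rng, bc, 1, kernel=1)
                      for _ in range(num_fg_classes + 1)]

    def decouple_branches(self, f) -> list:
        """Run the K+1 weight-independent branches on the deep feature."""
        return [branch(f) for branch in self.branches]

    def predict_masks(self, branch_features) -> PriorMaskSet:
        """1x1 heads + joint softmax over the K+1 branch logits per pixel."""
        logits = ag.concat(
            [head(feat) for head, feat in zip(self.heads, branch_features)], axis=1
        )
        masks = ag.softmax(logits, axis=1)
        k = self.num_fg_classes
        return PriorMaskSet(fg_masks=masks[:, :k], bg_mask=masks[:, k:],
                            logits=logits)

    def forward(self, f) -> PriorMaskSet:
        return self.predict_masks(self.decouple_branches(f))


def dynamic_weights(masks: PriorMaskSet, alpha: float = DEFAULT_ALPHA,
                    proportions: np.ndarray | None = None) -> DynamicWeightVector:
    """Per-class loss weights beta_k = 1 - sigmoid(alpha*(p_k - mu)).

    Proportions are the mean predicted foreground mask values over the batch
    and all pixels (detached); pass ``proportions`` explicitly to use
    ground-truth areas instead.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    k = masks.num_fg_classes
    if k < 1:
        raise ValueError("need at least one foreground class")
    if proportions is None:
        proportions = masks.fg_masks.data.mean(axis=(0, 2, 3))
    proportions = np.asarray(proportions, dtype=np.float64)
    mu = float(proportions.mean())
    beta = 1.0 - 1.0 / (1.0 + np.exp(-alpha * (proportions - mu)))
    return DynamicWeightVector(beta=beta, alpha=float(alpha), mu=mu,
                               proportions=proportions)


def dfm_loss(masks: PriorMaskSet, label_map: np.ndarray,
             alpha: float = DEFAULT_ALPHA,
             lambda_bg: float = DEFAULT_LAMBDA_BG,
             proportions_from: str = "pred") -> DFMLossBreakdown:
    """Dynamically weighted auxiliary loss sum_k beta_k L_k + lambda * L_bg.

    ``L_k = CE(y_k, g_k) + Dice(y_k, g_k)`` per foreground class, where g_k
    is the one-hot ground truth; the background target is the complement of
    the foreground union.  Masks at a coarser resolution than the labels are
    bilinearly upsampled first.
    """
    labels = np.asarray(label_map)
    if labels.ndim == 2:
        labels = labels[None]
    k = masks.num_fg_classes
    if labels.min() < 0 or labels.max() > k:
        raise ValueError(f"label values must lie in 0..{k}")
    h, w = labels.shape[1], labels.shape[2]
    ms = masks.resized(h, w)
    if ms.fg_masks.shape[0] != labels.shape[0]:
        raise ValueError("batch size mismatch between masks and labels")

    if proportions_from == "pred":
        weights = dynamic_weights(masks, alpha)
    elif proportions_from == "ground_truth":
        gt_props = np.array([(labels == c).mean() for c in range(1, k + 1)])
        weights = dynamic_weights(masks, alpha, proportions=gt_props)
    else:
        raise ValueError("proportions_from must be 'pred' or 'ground_truth'")

    per_class = []
    for c in range(1, k + 1):
        target = (labels == c).astype(np.float64)
        y = ms.fg_masks[:, c - 1]
        per_class.append(ce_loss(y, target) + dice_loss(y, target))
    bg_target = (labels == 0).astype(np.float64)
    bg_loss = ce_loss(ms.bg_mask[:, 0], bg_target) + dice_loss(ms.bg_mask[:, 0],
                                                               bg_target)
    total = None
    for beta_k, loss_k in zip(weights.beta, per_class):
        term = float(beta_k) * loss_k
        total = term if total is None else total + term
    total = total + lambda_bg * bg_loss
    return DFMLossBreakdown(per_class_losses=per_class, bg_loss=bg_loss,
                            weights=weights, total=total, lambda_bg=lambda_bg)
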