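"""Category-Aware Integration Aggregator (CAIA).

Attention-driven decoder fusion guided by the category prior masks.  The
fused decoder feature F_fuse (refined encoder skip concatenated with the
previous decoder output) is summarized into a compact class-context matrix

    C_ctx = F'_fuse^T Y'_prior          (C x (K+1) per batch item),

whose column k aggregates the feature mass of class k.  Queries come from
the K foreground prior masks (1x1 conv to an embedding of width d), keys
and values are learned linear maps of the context columns, and each pixel
attends over the K+1 class tokens:

    A = softmax(Q^T Keys / d),   F_att = Values A^T.

The attended feature is refined by a 1x1 convolution and added to the
decoder feature.  Attention is O(N*K), not O(N^2): pixels attend to class
summaries, never to each other.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .dfm import PriorMaskSet


@dataclasses.dataclass
class AttentionBundle:
    Q: Tensor        # (N, d, HW)
    Keys: Tensor     # (N, d, K+1)
    Values: Tensor   # (N, C, K+1)
    A: Tensor        # (N, HW, K+1), rows sum to 1
    F_att: Tensor    # (N, C, H, W)


def context_interaction(f_fuse, priors: PriorMaskSet) -> Tensor:
    """Class-context matrix C_ctx = F'^T Y' of shape (N, C, K+1).

    Priors are bilinearly resized to the fused feature's resolution first.
    """
    f_fuse = ag.as_tensor(f_fuse)
    n, c, h, w = f_fuse.shape
    pri = priors.resized(h, w)
    y = ag.reshape(pri.all_masks, (n, pri.num_fg_classes + 1, h * w))
    f_flat = ag.reshape(f_fuse, (n, c, h * w))
    # (N, C, HW) @ (N, HW, K+1)
    return ag.matmul(f_flat, ag.transpose(y, (0, 2, 1)))


class CAIA(nn.Module):
    """One decoder level of category-aware aggregation."""

    def __init__(self, rng, enc_channels: int, prev_channels: int | None,
                 out_channels: int, num_fg_classes: int, embed_dim: int = 16,
                 sqrt_scale: bool = False, detach_priors: bool = True,
                 use_attention: bool = True, concat_priors: bool = False,
                 zero_init_out: bool = False):
        super().__init__()
        if embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        self.num_fg_classes = num_fg_classes
        self.embed_dim = embed_dim
        self.sqrt_scale = sqrt_scale
        self.detach_priors = detach_priors
        self.use_attention = use_attention
        self.concat_priors = concat_priors
        self.refine = nn.conv_bn_relu(rng, enc_channels, out_channels)
        self.prev_mix = (
            nn.Conv2d(rng, out_channels + prev_channels, out_channels, kernel=1)
            if prev_channels else None
        )
        if use_attention:
            self.q_conv = nn.Conv2d(rng, num_fg_classes, embed_dim, kernel=1)
            self.key_map = nn.Linear(rng, out_channels, embed_dim)
            self.value_map = nn.Linear(rng, out_channels, out_channels)
            self.out_conv = nn.Conv2d(rng, out_channels, out_channels, kernel=1,
                                      zero_init=zero_init_out)
        elif concat_priors:
            self.prior_mix = nn.Conv2d(rng, out_channels + num_fg_classes + 1,
                                       out_channels, kernel=1)

    def build_fused(self, e_i, prev_decoder_out=None) -> Tensor:
        """3x3 refinement of the skip, concat with previous decoder output."""
        refined = self.refine(e_i)
        if prev_decoder_out is None:
            if self.prev_mix is not None:
                raise ValueError("this level expects a previous decoder output")
            return refined
        if self.prev_mix is None:
            raise ValueError("deepest level takes no previous decoder output")
        if prev_decoder_out.shape[2:] != refined.shape[2:]:
            raise ValueError(
                f"resolution mismatch: prev {prev_decoder_out.shape} vs "
                f"refined {refined.shape} (upsample prev first)"
            )
        return self.prev_mix(ag.concat([refined, prev_decoder_out], axis=1))

    def category_attention(self, priors: PriorMaskSet, ctx) -> AttentionBundle:
        """Class-token attention from pixel queries built on the fg priors."""
        q_maps = self.q_conv(priors.fg_masks)          # (N, d, H, W)
        n, d, h, w = q_maps.shape
        q = ag.reshape(q_maps, (n, d, h * w))
        keys = self.key_map(ctx)                        # (N, d, K+1)
        values = self.value_map(ctx)                    # (N, C, K+1)
        scale = np.sqrt(d) if self.sqrt_scale else float(d)
        scores = ag.matmul(ag.transpose(q, (0, 2, 1)), keys) * (1.0 / scale)
        attn = ag.softmax(scores, axis=-1)              # (N, HW, K+1)
        f_att = ag.matmul(values, ag.transpose(attn, (0, 2, 1)))
        c = values.shape[1]
        f_att = ag.reshape(f_att, (n, c, h, w))
        return AttentionBundle(Q=q, Keys=keys, Values=values, A=attn, F_att=f_att)

    def forward(self, e_i, prev_decoder_out, priors: PriorMaskSet | None,
                e_dec=None) -> Tensor:
        f_fuse = self.build_fused(e_i, prev_decoder_out)
        if e_dec is None:
            e_dec = f_fuse
        if not self.use_attention:
            if self.concat_priors and priors is not None:
                pri = priors.resized(f_fuse.shape[2], f_fuse.shape[3])
                if self.detach_priors:
                    pri = pri.detached()
                return self.prior_mix(ag.concat([f_fuse, pri.all_masks], axis=1))
            return f_fuse
        if priors is None:
            raise ValueError("category attention requires prior masks")
        pri = priors.resized(f_fuse.shape[2], f_fuse.shape[3])
        if self.detach_priors:
            pri = pri.detached()
        ctx = context_interaction(f_fuse, pri)
        # the raw context sums feature vectors over pixels, so its magnitude
        # grows with resolution; normalize by pixel count (class-average
        # feature mass) before the learned key/value maps
        ctx = ctx * (1.0 / (f_fuse.shape[2] * f_fuse.shape[3]))
        bundle = self.category_attention(pri, ctx)
        out = self.out_conv(bundle.F_att)
        if out.shape != e_dec.shape:
            raise ValueError(
                f"channel mismatch: attention output {out.shape} vs e_dec {e_dec.shape}"
            )
        return out + e_dec
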