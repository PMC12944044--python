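"""Dual-branch encoder: CNN stages and a pyramid-transformer tower coupled
per stage by Feature Coupling Units (FCUs).

Both branches run at the same stride per stage (4, 8, 16, 32 relative to
the input).  At each stage boundary the FCU projects the previous CNN
feature map into the next transformer stage's embedding space (1x1 conv →
average pool → layer norm → GELU), fuses it with the freshly patch-embedded
tokens by channel concatenation plus a learned 1x1 mix-down, and — on the
way out — reconstructs transformer semantics back into a CNN-shaped map
(1x1 conv → batch norm → ReLU → bilinear resize) so the per-stage skip
feature e_i seen by the decoder carries both branches.

With the FCU ablated the two branches run independently and are only
concatenated once at the deepest stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    stage_channels: tuple = (16, 32, 64, 96)
    transformer_depths: tuple = (1, 1, 1, 1)
    attention_heads: tuple = (1, 2, 4, 8)
    spatial_reduction: tuple = (8, 4, 2, 1)
    mlp_ratio: int = 2
    input_channels: int = 1

    def __post_init__(self):
        for name in ("stage_channels", "transformer_depths", "attention_heads",
                     "spatial_reduction"):
            vals = getattr(self, name)
            if len(vals) != 4 or any(v < (0 if name == "transformer_depths" else 1)
                                     for v in vals):
                raise ValueError(f"{name} must be 4 non-negative values")
        for c, h in zip(self.stage_channels, self.attention_heads):
            if c % h:
                raise ValueError(f"width {c} not divisible by heads {h}")


STAGE_STRIDES = (4, 8, 16, 32)
_STAGE_FACTORS = (4, 2, 2, 2)  # per-stage downsampling factors


class CNNStage(nn.Module):
    """Strided entry convolution followed by two 3x3 conv-BN-ReLU blocks."""

    def __init__(self, rng, in_ch, out_ch, factor):
        super().__init__()
        self.factor = factor
        self.entry = nn.conv_bn_relu(rng, in_ch, out_ch, kernel=factor,
                                     stride=factor, padding=0)
        self.block1 = nn.conv_bn_relu(rng, out_ch, out_ch)
        self.block2 = nn.conv_bn_relu(rng, out_ch, out_ch)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % self.factor or w % self.factor:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by stage factor {self.factor}"
            )
        return self.block2(self.block1(self.entry(x)))


class SpatialReductionAttention(nn.Module):
    """Multi-head self-attention whose keys/values come from a spatially
    reduced copy of the token grid (strided conv + layer norm)."""

    def __init__(self, rng, channels, heads, sr_ratio):
        super().__init__()
        self.heads = heads
        self.head_dim = channels // heads
        self.sr_ratio = sr_ratio
        self.q = nn.Conv2d(rng, channels, channels, kernel=1)
        self.kv_src_norm = None
        if sr_ratio > 1:
            self.sr = nn.Conv2d(rng, channels, channels, kernel=sr_ratio,
                                stride=sr_ratio)
            self.kv_src_norm = nn.LayerNorm2d(channels)
        self.k = nn.Conv2d(rng, channels, channels, kernel=1)
        self.v = nn.Conv2d(rng, channels, channels, kernel=1)
        self.proj = nn.Conv2d(rng, channels, channels, kernel=1)
        self.last_attention: np.ndarray | None = None

    def forward(self, x):
        n, c, h, w = x.shape
        src = x
        if self.sr_ratio > 1 and h >= self.sr_ratio and w >= self.sr_ratio:
            src = self.kv_src_norm(self.sr(x))
        q = self.q(x)
        k = self.k(src)
        v = self.v(src)
        m = src.shape[2] * src.shape[3]
        hd = self.head_dim

        def split_heads(t, length):
            t = ag.reshape(t, (n, self.heads, hd, length))
            return t

        qh = split_heads(ag.reshape(q, (n, c, h * w)), h * w)
        kh = split_heads(ag.reshape(k, (n, c, m)), m)
        vh = split_heads(ag.reshape(v, (n, c, m)), m)
        scores = ag.matmul(ag.transpose(qh, (0, 1, 3, 2)), kh) * (1.0 / np.sqrt(hd))
        attn = ag.softmax(scores, axis=-1)          # (n, heads, HW, M)
        self.last_attention = attn.data
        out = ag.matmul(vh, ag.transpose(attn, (0, 1, 3, 2)))  # (n, heads, hd, HW)
        out = ag.reshape(out, (n, c, h, w))
        return self.proj(out)


class TransformerBlock(nn.Module):
    def __init__(self, rng, channels, heads, sr_ratio, mlp_ratio):
        super().__init__()
        self.norm1 = nn.LayerNorm2d(channels)
        self.attn = SpatialReductionAttention(rng, channels, heads, sr_ratio)
        self.norm2 = nn.LayerNorm2d(channels)
        hidden = channels * mlp_ratio
        self.mlp = nn.Sequential(
            nn.Conv2d(rng, channels, hidden, kernel=1),
            nn.GELU(),
            nn.Conv2d(rng, hidden, channels, kernel=1),
        )

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class PatchEmbed(nn.Module):
    """Non-overlapping patch embedding: strided conv + layer norm."""

    def __init__(self, rng, in_ch, out_ch, factor):
        super().__init__()
        self.factor = factor
        self.proj = nn.Conv2d(rng, in_ch, out_ch, kernel=factor, stride=factor)
        self.norm = nn.LayerNorm2d(out_ch)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % self.factor or w % self.factor:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by patch stride {self.factor}"
            )
        return self.norm(self.proj(x))


class TransformerStage(nn.Module):
    def __init__(self, rng, in_ch, out_ch, factor, depth, heads, sr_ratio, mlp_ratio):
        super().__init__()
        self.patch_embed = PatchEmbed(rng, in_ch, out_ch, factor)
        self.blocks = [TransformerBlock(rng, out_ch, heads, sr_ratio, mlp_ratio)
                       for _ in range(depth)]

    def forward(self, x, fuse_fn=None):
        """Patch-embed ``x``; optionally fuse FCU output before the blocks."""
        tokens = self.patch_embed(x)
        if fuse_fn is not None:
            tokens = fuse_fn(tokens)
        for block in self.blocks:
            tokens = block(tokens)
        return tokens


class FCUProject(nn.Module):
    """Conv 1x1 → AvgPool → LayerNorm → GELU: align a CNN map to a token grid."""

    def __init__(self, rng, cnn_ch, token_ch):
        super().__init__()
        self.conv = nn.Conv2d(rng, cnn_ch, token_ch, kernel=1)
        self.norm = nn.LayerNorm2d(token_ch)

    def forward(self, cnn_feat, target_hw):
        h, w = cnn_feat.shape[2], cnn_feat.shape[3]
        th, tw = target_hw
        if h < th or w < tw:
            raise ValueError(
                f"projection only compresses: source {h}x{w} < target {th}x{tw}"
            )
        if h % th or w % tw or (h // th) != (w // tw):
            raise ValueError(f"source {h}x{w} not an integer multiple of {th}x{tw}")
        x = self.conv(cnn_feat)
        x = ag.avg_pool2d(x, h // th)
        return ag.gelu(self.norm(x))


class FCUFuse(nn.Module):
    """Channel-wise concatenation followed by a learned 1x1 mix-down."""

    def __init__(self, rng, ch_a, ch_b, out_ch):
        super().__init__()
        self.mix = nn.Conv2d(rng, ch_a + ch_b, out_ch, kernel=1)

    def forward(self, projected, tokens):
        if projected.shape[2:] != tokens.shape[2:]:
            raise ValueError(
                f"spatial mismatch: projected {projected.shape} vs tokens {tokens.shape}"
            )
        return self.mix(ag.concat([projected, tokens], axis=1))


class FCUReconstruct(nn.Module):
    """Conv 1x1 → BatchNorm → ReLU → bilinear resize back to a CNN grid."""

    def __init__(self, rng, token_ch, out_ch):
        super().__init__()
        self.conv = nn.Conv2d(rng, token_ch, out_ch, kernel=1, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, tokens, target_hw):
        th, tw = target_hw
        if th < tokens.shape[2] or tw < tokens.shape[3]:
            raise ValueError("reconstruction only upsamples or keeps resolution")
        x = ag.relu(self.bn(self.conv(tokens)))
        if (tokens.shape[2], tokens.shape[3]) != (th, tw):
            x = ag.resize_bilinear(x, th, tw)
        return x


class FCU(nn.Module):
    """One stage boundary's Feature Coupling Unit (project + fuse)."""

    def __init__(self, rng, cnn_ch, token_ch):
        super().__init__()
        self.projector = FCUProject(rng, cnn_ch, token_ch)
        self.fuser = FCUFuse(rng, token_ch, token_ch, token_ch)

    def project(self, cnn_feat, target_hw):
        return self.projector(cnn_feat, target_hw)

    def fuse(self, projected, tokens):
        return self.fuser(projected, tokens)


@dataclasses.dataclass
class FeaturePyramid:
    """Per-stage encoder outputs: CNN maps, token grids and fused skips."""

    cnn: list            # 4 tensors
    tokens: list         # 4 tensors
    fused: list          # 4 tensors (e_1..e_4)
    deep: Tensor         # f

    @property
    def strides(self):
        return STAGE_STRIDES


class DualEncoder(nn.Module):
    """Four coupled CNN/transformer stages producing e_1..e_4 and f."""

    def __init__(self, rng, config: EncoderConfig, use_fcu: bool = True):
        super().__init__()
        self.config = config
        self.use_fcu = use_fcu
        chans = config.stage_channels
        in_chs = (config.input_channels,) + chans[:3]
        self.cnn_stages = [
            CNNStage(rng, in_chs[i], chans[i], _STAGE_FACTORS[i]) for i in range(4)
        ]
        self.transformer_stages = [
            TransformerStage(rng, in_chs[i], chans[i], _STAGE_FACTORS[i],
                             config.transformer_depths[i],
                             config.attention_heads[i],
                             config.spatial_reduction[i],
                             config.mlp_ratio)
            for i in range(4)
        ]
        if use_fcu:
            # fcus[i] couples stage i+1 (projection of cnn_i into stage i+1 tokens)
            self.fcus = [FCU(rng, chans[i], chans[i + 1]) for i in range(3)]
            # per-stage output fusion: concat(cnn_i, reconstructed tokens) → e_i
            self.out_recon = [FCUReconstruct(rng, chans[i], chans[i])
                              for i in range(4)]
            self.out_mix = [nn.Conv2d(rng, 2 * chans[i], chans[i], kernel=1)
                            for i in range(4)]
        else:
            self.deep_mix = nn.Conv2d(rng, 2 * chans[3], chans[3], kernel=1)

    def forward(self, image) -> FeaturePyramid:
        image = ag.as_tensor(image)
        h, w = image.shape[2], image.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        cnn_feats, token_feats, fused = [], [], []
        c_prev = t_prev = image
        for i in range(4):
            c = self.cnn_stages[i](c_prev)
            if self.use_fcu and i > 0:
                fcu = self.fcus[i - 1]
                target_hw = (c.shape[2], c.shape[3])

                def fuse_fn(tokens, _fcu=fcu, _src=c_prev):
                    projected = _fcu.project(_src, (tokens.shape[2], tokens.shape[3]))
                    return _fcu.fuse(projected, tokens)

                t = self.transformer_stages[i](t_prev, fuse_fn)
            else:
                t = self.transformer_stages[i](t_prev)
            if self.use_fcu:
                recon = self.out_recon[i](t, (c.shape[2], c.shape[3]))
                e = self.out_mix[i](ag.concat([c, recon], axis=1))
            else:
                e = c
            cnn_feats.append(c)
            token_feats.append(t)
            fused.append(e)
            c_prev, t_prev = c, t
        if self.use_fcu:
            deep = fused[3]
        else:
            # ablated coupling: single concatenation at the deepest stage
            deep = self.deep_mix(ag.concat([cnn_feats[3], token_feats[3]], axis=1))
            fused[3] = deep
        return FeaturePyramid(cnn=cnn_feats, tokens=token_feats, fused=fused,
                              deep=deep)
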