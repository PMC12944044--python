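"""Full network assembly: dual encoder, DFM head, category-aware decoder.

The decoder starts at the deepest fused skip, alternates category-aware
aggregation with 2x bilinear upsampling up to stride 4, then jumps to the
input resolution with a final 4x bilinear upsampling and a 1x1 head that
produces K+1 logits.  Prior masks are predicted once from the deep feature
and bilinearly resized at every decoder level.

Ablation variants mirror the module toggles:

    (a) use_fcu=False, use_dfm=False, use_caia=False — branches concatenated
        once at the deep stage, plain convolutional decoder;
    (b) + FCU;
    (c) + DFM, priors concatenated into each decoder level (no attention);
    (d) + CAIA — the full model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .caia import CAIA
from .dfm import DEFAULT_ALPHA, DEFAULT_LAMBDA_BG, DecoupledFeatureModule, PriorMaskSet
from .encoder import DualEncoder, EncoderConfig


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = EncoderConfig()
    num_classes: int = 3                      # K foreground classes
    decoder_channels: tuple = (16, 32, 64, 96)
    dfm_alpha: float = DEFAULT_ALPHA
    dfm_lambda_bg: float = DEFAULT_LAMBDA_BG
    caia_embed_dim: int = 16
    caia_sqrt_scale: bool = False
    caia_detach_priors: bool = True
    use_fcu: bool = True
    use_dfm: bool = True
    use_caia: bool = True
    preset: str = "tiny"

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if len(self.decoder_channels) != 4 or any(c < 1 for c in self.decoder_channels):
            raise ValueError("decoder_channels must be 4 positive widths")
        if self.use_caia and not self.use_dfm:
            raise ValueError("CAIA requires DFM priors: use_caia needs use_dfm")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder"] = dataclasses.asdict(self.encoder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        enc = d.pop("encoder", {})
        for key in ("stage_channels", "transformer_depths", "attention_heads",
                    "spatial_reduction"):
            if key in enc:
                enc[key] = tuple(enc[key])
        if "decoder_channels" in d:
            d["decoder_channels"] = tuple(d["decoder_channels"])
        return cls(encoder=EncoderConfig(**enc), **d)


def tiny_config(num_classes: int = 3, **overrides) -> ModelConfig:
    """Desk-scale preset: 64x64 single-channel inputs, < 1M parameters."""
    return ModelConfig(num_classes=num_classes, preset="tiny", **overrides)


def full_config(num_classes: int = 8, **overrides) -> ModelConfig:
    """Full-fidelity preset mirroring a PVT-b0-sized tower on 224x224 RGB."""
    enc = EncoderConfig(
        stage_channels=(32, 64, 160, 256),
        transformer_depths=(2, 2, 2, 2),
        attention_heads=(1, 2, 5, 8),
        spatial_reduction=(8, 4, 2, 1),
        mlp_ratio=4,
        input_channels=3,
    )
    return ModelConfig(encoder=enc, num_classes=num_classes,
                       decoder_channels=(32, 64, 160, 256), preset="full",
                       **overrides)


@dataclasses.dataclass
class SegOutput:
    logits: Tensor                 # (N, K+1, H, W) at input resolution
    priors: PriorMaskSet | None    # deep-level prior masks (None if DFM ablated)
    aux: list                      # per-level decoder features, deepest first


class DCANet(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.num_classes
        self.encoder = DualEncoder(rng, config.encoder, use_fcu=config.use_fcu)
        deep_ch = config.encoder.stage_channels[3]
        self.dfm = (DecoupledFeatureModule(rng, deep_ch, k)
                    if config.use_dfm else None)
        dec = config.decoder_channels
        enc_ch = config.encoder.stage_channels
        self.decoder_levels = []
        prev = None
        for level in (3, 2, 1, 0):
            self.decoder_levels.append(
                CAIA(rng, enc_ch[level], prev, dec[level], k,
                     embed_dim=config.caia_embed_dim,
                     sqrt_scale=config.caia_sqrt_scale,
                     detach_priors=config.caia_detach_priors,
                     use_attention=config.use_caia,
                     concat_priors=config.use_dfm and not config.use_caia)
            )
            prev = dec[level]
        self.head = nn.Conv2d(rng, dec[0], k + 1, kernel=1)

    def forward(self, image) -> SegOutput:
        image = ag.as_tensor(image)
        if image.ndim == 3:
            image = ag.reshape(image, (1,) + image.shape)
        h, w = image.shape[2], image.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        pyramid = self.encoder(image)
        priors = self.dfm(pyramid.deep) if self.dfm is not None else None
        aux = []
        x = None
        for level_module, level in zip(self.decoder_levels, (3, 2, 1, 0)):
            if x is not None:
                e = pyramid.fused[level]
                x = ag.resize_bilinear(x, e.shape[2], e.shape[3])
            x = level_module(pyramid.fused[level], x, priors)
            aux.append(x)
        x = ag.resize_bilinear(x, h, w)
        logits = self.head(x)
        return SegOutput(logits=logits, priors=priors, aux=aux)

    def predict(self, image) -> np.ndarray:
        """Argmax label map for one H×W or H×W×C image (ties break toward
        the lower class index, i.e. background-favoring)."""
        batch = image_to_batch(image, self.config.encoder.input_channels)
        out = self.forward(batch)
        return np.argmax(out.logits.data, axis=1)[0].astype(np.uint8)


def ablation_variant(flags: dict, base: ModelConfig | None = None,
                     seed: int = 0) -> DCANet:
    """Build a model variant from {use_fcu, use_dfm, use_caia} toggles."""
    base = base or tiny_config()
    cfg = dataclasses.replace(base, use_fcu=bool(flags.get("use_fcu", True)),
                              use_dfm=bool(flags.get("use_dfm", True)),
                              use_caia=bool(flags.get("use_caia", True)))
    return DCANet(cfg, seed=seed)


def image_to_batch(image: np.ndarray, input_channels: int) -> np.ndarray:
    """HxW or HxWxC float image → 1xCxHxW batch, replicating gray to C."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    elif image.ndim == 3:
        image = np.transpose(image, (2, 0, 1))
    if image.shape[0] == 1 and input_channels > 1:
        image = np.repeat(image, input_channels, axis=0)
    if image.shape[0] != input_channels:
        raise ValueError(
            f"image has {image.shape[0]} channels, model expects {input_channels}"
        )
    return image[None]
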