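"""The connected dual U-Net.

The first U-Net maps a CT slice to a pseudo-PET intensity image; the second
U-Net maps the CT slice (concatenated channel-wise with the pseudo-PET) to a
tumor-probability map.  The two networks are "connected": each decoder stage
of the first U-Net feeds its feature map into the resolution-matched encoder
stage of the second U-Net (cross-network skip concatenation), so the learned
PET representation guides segmentation at every scale.

Every block is two 3x3 padded convolutions, each followed by instance
normalization and a leaky ReLU; downsampling is 2x2 max pooling with stride 2;
upsampling is a learnable 2x2 stride-2 transposed convolution (nearest-
neighbor + 3x3 convolution available behind ``upsample_mode``).  Channel
width doubles at every resolution level.  The PET head is linear (trained
against intensity-normalized PET in [0, 1]); the segmentation head ends in a
sigmoid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "ConnectedOutput",
    "EncoderStage",
    "DecoderStage",
    "UNet",
    "ConnectedUNet",
    "encoder_stage",
    "decoder_stage",
    "forward_first_unet",
    "forward_connected",
    "count_trainable_parameters",
    "save_checkpoint_weights",
    "load_checkpoint_weights",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the connected dual U-Net.

    ``base_width`` is the channel count at the highest resolution level and
    doubles at each of the ``depth`` levels.  The published configuration is
    base_width 48, depth 5 (tests use base_width 8 for speed).
    """

    in_channels: int = 1
    base_width: int = 48
    depth: int = 5
    leaky_slope: float = 0.01
    norm: str = "instance"  # "instance" or "none"
    norm_affine: bool = True
    pet_out_channels: int = 1
    seg_out_channels: int = 1
    activation_first: bool = False  # True: LeakyReLU -> Conv -> Norm ordering
    upsample_mode: str = "transposed"  # "transposed" or "nearest"
    seg_head_bias: float = -2.0  # foreground-prior initialization of the seg head

    def __post_init__(self):
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        if self.upsample_mode not in ("transposed", "nearest"):
            raise ValueError("upsample_mode must be 'transposed' or 'nearest'")

    def width(self, level: int) -> int:
        """Channel width at 1-based resolution level."""
        return self.base_width * 2 ** (level - 1)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass
class ConnectedOutput:
    """One forward pass of the dual network: pseudo-PET and tumor probability."""

    pseudo_pet: np.ndarray  # (B, 1, H, W), unbounded intensities
    seg_prob: np.ndarray    # (B, 1, H, W), entries in [0, 1]


class ConvBlock(nn.Module):
    """3x3 convolution + instance norm + leaky ReLU (order configurable)."""

    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.slope = cfg.leaky_slope
        self.activation_first = cfg.activation_first
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.norm = (nn.InstanceNorm2d(out_ch, affine=cfg.norm_affine)
                     if cfg.norm == "instance" else None)

    def __call__(self, x: Tensor) -> Tensor:
        if self.activation_first:
            x = nn.leaky_relu(x, self.slope)
            x = self.conv(x)
            return self.norm(x) if self.norm is not None else x
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return nn.leaky_relu(x, self.slope)


class DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.block1 = ConvBlock(in_ch, out_ch, cfg, rng)
        self.block2 = ConvBlock(out_ch, out_ch, cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class EncoderStage(nn.Module):
    """Two convolution blocks followed by 2x2 stride-2 max pooling."""

    def __init__(self, in_channels: int, level: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.convs = DoubleConv(in_channels, cfg.width(level), cfg, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"encoder stage requires even spatial dims, got {(h, w)}")
        skip = self.convs(x)
        return skip, nn.max_pool2d(skip)


class DecoderStage(nn.Module):
    """Upsample deep features, concatenate the matching skip, two conv blocks."""

    def __init__(self, deep_channels: int, skip_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        self.mode = cfg.upsample_mode
        if self.mode == "transposed":
            self.up = nn.ConvTranspose2d(deep_channels, skip_channels, rng=rng)
        else:
            self.up = nn.Conv2d(deep_channels, skip_channels, 3, padding=1, rng=rng)
        self.convs = DoubleConv(2 * skip_channels, skip_channels, cfg, rng)

    def _upsample(self, deep: Tensor) -> Tensor:
        if self.mode == "transposed":
            return self.up(deep)
        b, c, h, w = deep.shape

        def backward(g):
            if deep.requires_grad:
                deep._accum(g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))

        rep = Tensor._result(np.repeat(np.repeat(deep.data, 2, axis=2), 2, axis=3),
                             (deep,), backward)
        return self.up(rep)

    def __call__(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self._upsample(deep)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"decoder stage: upsampled {up.shape[2:]} does not match skip {skip.shape[2:]}")
        return self.convs(nn.concat([up, skip], axis=1))


class OutputHead(nn.Module):
    """One 3x3 convolution block then a 1x1 output convolution (linear)."""

    def __init__(self, width: int, out_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator, bias_init: float = 0.0):
        self.block = ConvBlock(width, width, cfg, rng)
        self.out = nn.Conv2d(width, out_channels, 1, padding=0, rng=rng)
        if bias_init:
            self.out.bias.data[:] = np.float32(bias_init)

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.block(x))


class UNet(nn.Module):
    """One encoder–decoder network.

    ``cross_channels[k]`` extra channels are concatenated into encoder level
    k+1's input (used by the second U-Net to receive the first U-Net's decoder
    features); the bottleneck level receives none.
    """

    def __init__(self, in_channels: int, out_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator, cross_channels: list[int] | None = None,
                 head_bias: float = 0.0):
        self.cfg = cfg
        d = cfg.depth
        cross = cross_channels or [0] * (d - 1)
        if len(cross) != d - 1:
            raise ValueError("cross_channels must have depth-1 entries")
        self.encoders = []
        for level in range(1, d):
            cin = (in_channels if level == 1 else cfg.width(level - 1)) + cross[level - 1]
            self.encoders.append(EncoderStage(cin, level, cfg, rng))
        self.bottleneck = DoubleConv(cfg.width(d - 1), cfg.width(d), cfg, rng)
        self.decoders = [DecoderStage(cfg.width(level + 1), cfg.width(level), cfg, rng)
                         for level in range(d - 1, 0, -1)]
        self.head = OutputHead(cfg.base_width, out_channels, cfg, rng,
                               bias_init=head_bias)

    def __call__(self, x: Tensor, cross: list[Tensor] | None = None
                 ) -> tuple[Tensor, list[Tensor]]:
        """Returns (head output, decoder feature maps coarsest-first)."""
        d = self.cfg.depth
        _, _, h, w = x.shape
        div = 2 ** (d - 1)
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {(h, w)} must be divisible by 2^(depth-1) = {div}")
        skips: list[Tensor] = []
        for level, enc in enumerate(self.encoders, start=1):
            if cross is not None:
                x = nn.concat([x, cross[level - 1]], axis=1)
            skip, x = enc(x)
            skips.append(skip)
        x = self.bottleneck(x)
        decoder_feats: list[Tensor] = []
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
            decoder_feats.append(x)
        return self.head(x), decoder_feats


class ConnectedUNet(nn.Module):
    """The dual network: CT -> pseudo-PET -> (CT, pseudo-PET) -> tumor map."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.unet1 = UNet(c.in_channels, c.pet_out_channels, c, rng)
        # decoder features arrive coarsest-first; encoder level k (fine-first)
        # receives the feature map at its own resolution
        cross = [c.width(level) for level in range(1, c.depth)]
        # the seg head starts at the sparse-foreground prior so early training
        # is not spent suppressing background
        self.unet2 = UNet(c.in_channels + c.pet_out_channels, c.seg_out_channels,
                          c, rng, cross_channels=cross,
                          head_bias=c.seg_head_bias)

    def forward_first(self, ct: Tensor) -> tuple[Tensor, list[Tensor]]:
        return self.unet1(ct)

    def forward_tensors(self, ct: Tensor) -> tuple[Tensor, Tensor]:
        """Full forward pass; returns (pseudo-PET, segmentation logits)."""
        pet, decoder_feats = self.unet1(ct)
        x2 = nn.concat([ct, pet], axis=1)
        # decoder_feats[j] lives at resolution level depth-1-j; encoder level k
        # (1-based, fine to coarse) needs resolution level k
        cross = list(reversed(decoder_feats))
        seg_logit, _ = self.unet2(x2, cross=cross)
        return pet, seg_logit

    def __call__(self, ct) -> ConnectedOutput:
        t = ct if isinstance(ct, Tensor) else Tensor(np.asarray(ct, dtype=np.float32))
        pet, seg_logit = self.forward_tensors(t)
        return ConnectedOutput(pseudo_pet=pet.data.copy(),
                               seg_prob=nn.sigmoid(seg_logit).data.copy())


# ---------------------------------------------------------------------------
# functional wrappers (deterministically seeded when no module is supplied)
# ---------------------------------------------------------------------------

def encoder_stage(x, level: int, config: ModelConfig, rng=None):
    """Apply one freshly initialized encoder stage; returns (skip, pooled)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    stage = EncoderStage(x.shape[1], level, config, rng)
    return stage(x)


def decoder_stage(deep, skip, config: ModelConfig, rng=None):
    """Apply one freshly initialized decoder stage."""
    rng = rng if rng is not None else np.random.default_rng(0)
    deep = deep if isinstance(deep, Tensor) else Tensor(np.asarray(deep, dtype=np.float32))
    skip = skip if isinstance(skip, Tensor) else Tensor(np.asarray(skip, dtype=np.float32))
    stage = DecoderStage(deep.shape[1], skip.shape[1], config, rng)
    return stage(deep, skip)


def forward_first_unet(ct, config: ModelConfig, model: ConnectedUNet | None = None,
                       seed: int = 0):
    """PET branch only; returns (pet map, decoder feature list)."""
    model = model or ConnectedUNet(config, seed=seed)
    t = ct if isinstance(ct, Tensor) else Tensor(np.asarray(ct, dtype=np.float32))
    return model.forward_first(t)


def forward_connected(ct, config: ModelConfig, model: ConnectedUNet | None = None,
                      seed: int = 0) -> ConnectedOutput:
    model = model or ConnectedUNet(config, seed=seed)
    return model(ct)


def count_trainable_parameters(config: ModelConfig | None = None) -> int:
    """Exact number of trainable scalars of the full dual network."""
    return ConnectedUNet(config or ModelConfig(), seed=0).num_parameters()


# ---------------------------------------------------------------------------
# checkpoint I/O: npz weight container + self-describing JSON sidecar
# ---------------------------------------------------------------------------

def save_checkpoint_weights(path, model_state: dict, teacher_state: dict | None,
                            config: ModelConfig, meta: dict | None = None) -> None:
    path = Path(path)
    arrays = {f"model/{k}": v for k, v in model_state.items()}
    if teacher_state is not None:
        arrays.update({f"teacher/{k}": v for k, v in teacher_state.items()})
    np.savez(path, **arrays)
    sidecar = {"config": dataclasses.asdict(config), **(meta or {})}
    real = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    real.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_checkpoint_weights(path):
    """Returns (model_state, teacher_state or None, ModelConfig, meta dict)."""
    path = Path(path)
    with np.load(path) as z:
        model_state = {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")}
        teacher_state = {k[len("teacher/"):]: z[k] for k in z.files
                         if k.startswith("teacher/")} or None
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar.pop("config"))
    return model_state, teacher_state, config, sidecar
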