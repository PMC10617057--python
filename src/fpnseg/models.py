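"""Segmentation networks: baseline U-Net and the U-Net/FPN hybrid.

The hybrid keeps the U-Net contracting path as the bottom-up pathway and
replaces the expanding path with a feature-pyramid decoder: each of the four
post-downsampling encoder scales is reduced to a common width by a lateral
1x1 convolution; a top-down pathway upsamples the coarser merged map with
nearest-neighbor interpolation and adds it element-wise to the lateral map;
each merged level passes through two 3x3 convolutions; all levels are
upsampled to the finest pyramid resolution and concatenated (4 levels x 128
lateral channels = 512 at the default width); a 3x3 convolution with batch
normalization and ReLU fuses them, a 1x1 convolution produces logits, and a
final bilinear upsample restores the input resolution before the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .nn import Adam, ConvBNReLU, Module, Tensor  # noqa: F401  (Adam re-exported for callers)
from .nn import functional as F
from .nn.layers import Conv2d

__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "UNetEncoder",
    "FPNDecoder",
    "ImprovedFPN",
    "UNet",
    "build_encoder",
    "build_fpn_decoder",
    "baseline_unet",
    "build_model",
    "forward_batch",
    "predict_mask",
    "architecture_summary",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised when a model configuration is internally inconsistent."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_widths`` gives the channel count at the full-resolution stem
    and after each of the four downsamplings (canonical U-Net doubling by
    default).  ``lateral_channels`` is the common pyramid width; the fused
    tensor therefore has lateral_channels x 4 channels (512 by default).
    ``residual_encoder`` adds identity shortcuts around each encoder block
    (off by default).
    """

    input_size: Tuple[int, int, int] = (256, 256, 3)
    encoder_widths: Tuple[int, ...] = (64, 128, 256, 512, 1024)
    lateral_channels: int = 128
    head_threshold: float = 0.5
    head_bias_init: float = -2.0
    residual_encoder: bool = False
    seed: int = 0

    @property
    def n_downsamples(self) -> int:
        return len(self.encoder_widths) - 1

    @property
    def n_pyramid_levels(self) -> int:
        return self.n_downsamples

    @property
    def fused_channels(self) -> int:
        return self.lateral_channels * self.n_pyramid_levels

    def validate(self) -> None:
        h, w, c = self.input_size
        divisor = 2**self.n_downsamples
        if h % divisor or w % divisor:
            raise ConfigurationError(
                f"input size {h}x{w} not divisible by 2^{self.n_downsamples}"
            )
        if c != 3:
            raise ConfigurationError(f"expected 3 input channels, got {c}")
        if self.n_downsamples < 1:
            raise ConfigurationError("need at least one downsampling stage")

    @classmethod
    def small(cls, input_size: Tuple[int, int, int] = (64, 64, 3), seed: int = 0) -> "ModelConfig":
        """Reduced-width preset for CPU-scale training experiments."""
        return cls(
            input_size=input_size,
            encoder_widths=(8, 16, 32, 64, 128),
            lateral_channels=16,
            seed=seed,
        )

    @classmethod
    def medium(cls, input_size: Tuple[int, int, int] = (64, 64, 3), seed: int = 0) -> "ModelConfig":
        """Quarter-width preset: more capacity than `small`, still CPU-friendly."""
        return cls(
            input_size=input_size,
            encoder_widths=(16, 32, 64, 128, 256),
            lateral_channels=32,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# encoder (bottom-up pathway)


class _EncoderBlock(Module):
    """Two 3x3 conv-BN-ReLU layers, optionally wrapped with a residual shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, residual: bool):
        super().__init__()
        self.block1 = ConvBNReLU(cin, cout, rng)
        self.block2 = ConvBNReLU(cout, cout, rng)
        self.residual = residual
        self.proj = Conv2d(cin, cout, 1, rng, bias=False) if residual and cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.block2(self.block1(x))
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            y = F.add(y, shortcut)
        return y


class UNetEncoder(Module):
    """U-Net contracting path emitting the post-downsampling feature pyramid.

    Returns (stem, [c1..c4]) where ck has spatial size input / 2^k; the four
    downsampled scales are the pyramid levels fed to the FPN decoder, and
    the stem plus all scales serve as skip sources for the baseline U-Net.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        widths = config.encoder_widths
        self.stem = _EncoderBlock(config.input_size[2], widths[0], rng, config.residual_encoder)
        self.stages = [
            _EncoderBlock(widths[i], widths[i + 1], rng, config.residual_encoder)
            for i in range(config.n_downsamples)
        ]

    def forward(self, x: Tensor) -> Tuple[Tensor, List[Tensor]]:
        stem = self.stem(x)
        levels: List[Tensor] = []
        h = stem
        for stage in self.stages:
            h = stage(F.maxpool2x2(h))
            levels.append(h)
        return stem, levels


# ---------------------------------------------------------------------------
# FPN decoder (top-down pathway + multi-level fusion)


class FPNDecoder(Module):
    """Lateral 1x1 reductions, nearest-neighbor top-down merges, 512-ch fusion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        lc = config.lateral_channels
        widths = config.encoder_widths[1:]
        self.laterals = [Conv2d(wd, lc, 1, rng) for wd in widths]
        # two 3x3 convs refine each merged level before fusion
        self.refines = [_RefinePair(lc, rng) for _ in range(config.n_pyramid_levels)]
        self.fuse = ConvBNReLU(config.fused_channels, config.fused_channels, rng)
        self.head = Conv2d(config.fused_channels, 1, 1, rng)
        # background-prior initialisation: sigmoid(-2) ~ 0.12, so untrained
        # predictions start near background, which strengthens the Dice
        # gradient on the (rare) tumor pixels and speeds early convergence
        self.head.bias.data[:] = config.head_bias_init
        self.n_levels = config.n_pyramid_levels
        self.last_fused_channels: Optional[int] = None

    def forward(self, levels: List[Tensor], out_size: Tuple[int, int]) -> Tensor:
        if len(levels) != self.n_levels:
            raise ConfigurationError(
                f"expected {self.n_levels} pyramid levels, got {len(levels)}"
            )
        lat = [conv(x) for conv, x in zip(self.laterals, levels)]
        merged: List[Tensor] = [None] * self.n_levels  # type: ignore[list-item]
        top = lat[-1]
        merged[-1] = top
        for i in range(self.n_levels - 2, -1, -1):
            top = F.add(lat[i], F.upsample_nearest2d(top, 2))
            merged[i] = top
        refined = [refine(m) for refine, m in zip(self.refines, merged)]
        aligned = [refined[0]]
        for i in range(1, self.n_levels):
            aligned.append(F.upsample_nearest2d(refined[i], 2**i))
        fused = F.concat_channels(aligned)
        self.last_fused_channels = fused.shape[1]
        y = self.head(self.fuse(fused))
        y = F.upsample_bilinear2d(y, out_size)
        return F.sigmoid(y)


class _RefinePair(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.a = ConvBNReLU(channels, channels, rng)
        self.b = ConvBNReLU(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.b(self.a(x))


# ---------------------------------------------------------------------------
# full models


class ImprovedFPN(Module):
    """U-Net encoder fused with the FPN decoder (the proposed model)."""

    name = "improved_fpn"

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = UNetEncoder(config, rng)
        self.decoder = FPNDecoder(config, rng)

    def forward(self, x: Tensor) -> Tensor:
        _, levels = self.encoder(x)
        return self.decoder(levels, x.shape[2:])


class _UpBlock(Module):
    """Expanding-path stage: upsample, concat skip, two 3x3 conv-BN-ReLU."""

    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = Conv2d(cin, cout, 1, rng)
        self.block1 = ConvBNReLU(cout + cskip, cout, rng)
        self.block2 = ConvBNReLU(cout, cout, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.reduce(F.upsample_nearest2d(x, 2))
        x = F.concat_channels([x, skip])
        return self.block2(self.block1(x))


class UNet(Module):
    """Classical U-Net baseline: four down-/up-samples with skip concatenation."""

    name = "unet"

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = UNetEncoder(config, rng)
        widths = config.encoder_widths
        self.ups = [
            _UpBlock(widths[i + 1], widths[i], widths[i], rng)
            for i in range(config.n_downsamples - 1, -1, -1)
        ]
        self.head = Conv2d(widths[0], 1, 1, rng)
        self.head.bias.data[:] = config.head_bias_init  # same background prior

    def forward(self, x: Tensor) -> Tensor:
        stem, levels = self.encoder(x)
        skips = [stem] + levels[:-1]
        h = levels[-1]
        for up, skip in zip(self.ups, reversed(skips)):
            h = up(h, skip)
        return F.sigmoid(self.head(h))


def build_encoder(config: ModelConfig, seed: Optional[int] = None) -> UNetEncoder:
    """Standalone U-Net contracting path producing the feature pyramid."""
    return UNetEncoder(config, np.random.default_rng(config.seed if seed is None else seed))


def build_fpn_decoder(config: ModelConfig, seed: Optional[int] = None) -> FPNDecoder:
    """Standalone FPN decoder mapping a feature pyramid to a probability map."""
    config.validate()
    return FPNDecoder(config, np.random.default_rng(config.seed if seed is None else seed))


def baseline_unet(config: ModelConfig) -> "UNet":
    """The classical U-Net used as the comparison baseline."""
    return UNet(config)


def build_model(kind: str, config: ModelConfig) -> Module:
    """Construct a model by name: 'improved_fpn' or 'unet'."""
    if kind == "improved_fpn":
        return ImprovedFPN(config)
    if kind == "unet":
        return UNet(config)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# inference helpers


def forward_batch(model: Module, images: np.ndarray) -> np.ndarray:
    """Run a normalized H×W×3 image batch (N,H,W,3) through the model.

    Returns probability maps (N, H, W) in (0, 1); gradient-free.
    """
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3-channel input, got shape {arr.shape}")
    x = Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))
    out = model(x)
    return out.data[:, 0]


def predict_mask(probmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map at ``threshold`` (strict {0,1} output)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    arr = np.asarray(probmap)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (arr > threshold).astype(np.uint8)


def architecture_summary(model: Module) -> str:
    """Plain-text audit summary: parameter name, shape, count per tensor."""
    lines = [f"{'parameter':50s} {'shape':>18s} {'count':>10s}"]
    total = 0
    for name, p in model.named_parameters():
        total += p.data.size
        lines.append(f"{name:50s} {str(p.data.shape):>18s} {p.data.size:>10d}")
    lines.append(f"{'total':50s} {'':>18s} {total:>10d}")
    return "\n".join(lines)


def save_checkpoint(model: Module, path: Union[str, Path]) -> Path:
    """Serialize model weights (and batch-norm statistics) as an .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    return path


def load_checkpoint(model: Module, path: Union[str, Path]) -> Module:
    with np.load(Path(path)) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
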