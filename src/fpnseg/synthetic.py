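"""Synthetic brain-MRI phantoms with exact ground-truth tumor masks.

Each phantom is an RGB slice containing an elliptical "brain" with smooth
texture on a dark noisy background; with configurable probability the brain
carries one to three hyperintense tumor blobs — ellipses whose radius is
perturbed by low-order sinusoids, so the boundaries are irregular the way
real tumor outlines are.  The mask is the exact union of blob supports,
which makes every downstream module testable without any image download.

The default positive fraction (0.35) mirrors a cohort in which roughly a
third of slices show tumor; per-channel gains mimic the differing channel
intensities of RGB-exported multi-sequence MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import DEFAULT_MASK_SUFFIX, ImageRecord

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset", "read_manifest"]


@dataclass
class PhantomConfig:
    """Parameters of the phantom generator.

    tumor_radius_range is a fraction of the image side; tumor_contrast is
    the mean intensity (0–255 scale) added to tumor pixels over the local
    brain texture; blob_irregularity scales the sinusoidal boundary
    perturbation (0 = perfect ellipses).
    """

    image_size: Tuple[int, int] = (256, 256)
    tumor_probability: float = 0.35
    tumor_radius_range: Tuple[float, float] = (0.06, 0.16)
    blob_irregularity: float = 0.35
    tumor_contrast: float = 80.0
    noise_sigma: float = 8.0
    channel_gains: Tuple[float, float, float] = (1.0, 0.88, 0.78)
    brain_intensity: float = 110.0
    background_intensity: float = 18.0
    max_blobs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ValueError("tumor_probability must lie in [0, 1]")
        lo, hi = self.tumor_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("tumor radii must be positive fractions below 0.5")


@dataclass
class PhantomManifest:
    """Files written by generate_dataset with their positive/negative labels."""

    entries: List[Tuple[str, int]] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(label for _, label in self.entries)


def _ellipse_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    axes: Tuple[float, float],
    angle: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _blob_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deformed-ellipse blob: radius modulated by low-order sinusoids of angle."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)
    elong = rng.uniform(0.7, 1.3)
    modulation = np.ones_like(theta)
    for order in (2, 3, 5):
        amp = irregularity * rng.uniform(0.0, 0.25)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        modulation += amp * np.sin(order * theta + phase)
    base = radius * np.sqrt(elong * np.cos(theta) ** 2 + np.sin(theta) ** 2 / elong)
    return rr <= base * np.clip(modulation, 0.3, None)


def generate_phantom(
    config: PhantomConfig,
    rng: Optional[np.random.Generator] = None,
    force_tumor: Optional[bool] = None,
) -> ImageRecord:
    """Generate one phantom slice (uint8 RGB image, {0,1} mask).

    ``force_tumor`` overrides the Bernoulli(tumor_probability) draw when the
    caller needs a guaranteed positive or negative sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    side = min(h, w)

    # brain ellipse with randomized pose
    center = (h / 2 + rng.uniform(-0.04, 0.04) * h, w / 2 + rng.uniform(-0.04, 0.04) * w)
    axes = (rng.uniform(0.32, 0.40) * h, rng.uniform(0.26, 0.34) * w)
    brain = _ellipse_mask((h, w), center, axes, rng.uniform(0.0, np.pi))

    # smooth texture inside the brain
    texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=side / 16)
    texture *= 30.0 / max(texture.std(), 1e-9)
    base = np.full((h, w), config.background_intensity)
    base[brain] = config.brain_intensity + texture[brain]

    has_tumor = (
        bool(rng.random() < config.tumor_probability) if force_tumor is None else force_tumor
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    if has_tumor:
        # shrunken brain ellipse: candidate region that keeps blobs inside
        inner = _ellipse_mask((h, w), center, (axes[0] * 0.75, axes[1] * 0.75), 0.0)
        ys, xs = np.nonzero(inner)
        n_blobs = int(rng.integers(1, config.max_blobs + 1))
        for _ in range(n_blobs):
            i = int(rng.integers(len(ys)))
            radius = rng.uniform(*config.tumor_radius_range) * side
            blob = _blob_mask((h, w), (ys[i], xs[i]), radius, config.blob_irregularity, rng)
            mask |= (blob & brain).astype(np.uint8)
        if not mask.any():  # degenerate draw; paint a minimal guaranteed blob
            i = int(rng.integers(len(ys)))
            blob = _blob_mask(
                (h, w), (ys[i], xs[i]), config.tumor_radius_range[0] * side, 0.0, rng
            )
            mask |= (blob & brain).astype(np.uint8)
        base[mask.astype(bool)] += config.tumor_contrast

    base += rng.normal(0.0, config.noise_sigma, (h, w))
    image = np.clip(
        base[:, :, None] * np.asarray(config.channel_gains)[None, None, :], 0, 255
    ).astype(np.uint8)
    return ImageRecord(image=image, mask=mask, id=f"phantom_{rng.bit_generator.seed_seq.entropy}")


def generate_dataset(
    n: int,
    config: PhantomConfig,
    out_dir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> Tuple[List[ImageRecord], PhantomManifest]:
    """Generate ``n`` phantoms; optionally write PNGs + a plain-text manifest.

    Files follow the loader's naming rule (``<id>.png`` / ``<id>_mask.png``);
    the manifest lists ``<path><TAB><label>`` per line.  Deterministic for a
    given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root_seed = config.seed if seed is None else seed
    records: List[ImageRecord] = []
    manifest = PhantomManifest()
    for i in range(n):
        rng = np.random.default_rng((root_seed, i))
        rec = generate_phantom(config, rng)
        rec.id = f"phantom_{root_seed}_{i:04d}"
        rec.patient_id = f"patient_{i % max(1, n // 12)}"
        records.append(rec)
        manifest.entries.append((f"{rec.id}.png", int(rec.is_positive)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            Image.fromarray(rec.image).save(out_dir / f"{rec.id}.png")
            Image.fromarray(rec.mask * 255).save(out_dir / f"{rec.id}{DEFAULT_MASK_SUFFIX}.png")
        lines = "".join(f"{name}\t{label}\n" for name, label in manifest.entries)
        (out_dir / "manifest.tsv").write_text(lines)
    return records, manifest


def read_manifest(path: Union[str, Path]) -> PhantomManifest:
    manifest = PhantomManifest()
    for line in Path(path).read_text().splitlines():
        name, label = line.split("\t")
        manifest.entries.append((name, int(label)))
    return manifest
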