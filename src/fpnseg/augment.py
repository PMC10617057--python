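"""Paired image/mask augmentation with reproducible randomness.

Nine operations are supported, applied independently per sample in a fixed
order: horizontal shift, transpose, vertical shift, blur, random crop,
random rotate, random resize, random flip, random brightness.  Geometric
transforms are applied identically to image and mask (mask resampled with
nearest-neighbor so it stays strictly binary); photometric transforms (blur,
brightness) touch the image only.  Output shape always equals input shape —
crops and zooms are resized or padded back.

Parameter semantics (the conventions of mainstream augmentation tooling):
shift parameters and random_resize are maximum fractional magnitudes drawn
uniformly from ±range each sample; random_brightness is the width of a
multiplicative jitter around 1; transpose, blur, random_crop, random_rotate
and random_flip are application probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import FrozenSet, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .data import ImageRecord

__all__ = ["AugmentationConfig", "augment_pair", "preview_grid"]

OP_NAMES = (
    "horizontal_shift",
    "transpose",
    "vertical_shift",
    "blur",
    "random_crop",
    "random_rotate",
    "random_resize",
    "random_flip",
    "random_brightness",
)


@dataclass(frozen=True)
class AugmentationConfig:
    """The nine augmentation operations and their parameters.

    Defaults follow the study protocol; ``enabled`` switches the whole
    pipeline, ``disabled_ops`` switches individual operations off.
    """

    horizontal_shift: float = 0.25
    transpose: float = 0.25
    vertical_shift: float = 0.25
    blur: float = 0.05
    random_crop: float = 0.05
    random_rotate: float = 0.5
    random_resize: float = 0.25
    random_flip: float = 0.5
    random_brightness: float = 1.0
    enabled: bool = True
    disabled_ops: FrozenSet[str] = frozenset()
    max_rotation_deg: float = 30.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in OP_NAMES and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        for name in ("transpose", "blur", "random_crop", "random_rotate", "random_flip"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a probability and must be <= 1")
        unknown = set(self.disabled_ops) - set(OP_NAMES)
        if unknown:
            raise ValueError(f"unknown ops in disabled_ops: {sorted(unknown)}")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A configuration under which augment_pair is the identity."""
        return cls(**{name: 0.0 for name in OP_NAMES})

    def active(self, name: str) -> float:
        if not self.enabled or name in self.disabled_ops:
            return 0.0
        return getattr(self, name)


def _resize_pair(
    image: np.ndarray, mask: np.ndarray, shape: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    image = _sk_resize(image, shape + image.shape[2:], order=1, preserve_range=True,
                       anti_aliasing=False).astype(np.float32)
    mask = _sk_resize(mask, shape, order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.uint8)
    return image, mask


def augment_pair(
    record: ImageRecord,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> ImageRecord:
    """Apply the configured augmentations to a normalized, binarized record.

    Same seed, config and input yield bit-identical output.  Degenerate
    (zero-magnitude / zero-probability) operations are skipped entirely, so
    the identity config is an exact no-op.
    """
    image = np.asarray(record.image, dtype=np.float32)
    mask = np.asarray(record.mask, dtype=np.uint8)
    h, w = mask.shape

    # 1-3. shifts and transpose
    m = config.active("horizontal_shift")
    if m > 0:
        dx = rng.uniform(-m, m) * w
        image = ndimage.shift(image, (0.0, dx, 0.0), order=1, cval=0.0)
        mask = ndimage.shift(mask, (0.0, dx), order=0, cval=0)
    p = config.active("transpose")
    if p > 0 and rng.random() < p and h == w:
        image = np.ascontiguousarray(image.swapaxes(0, 1))
        mask = np.ascontiguousarray(mask.swapaxes(0, 1))
    m = config.active("vertical_shift")
    if m > 0:
        dy = rng.uniform(-m, m) * h
        image = ndimage.shift(image, (dy, 0.0, 0.0), order=1, cval=0.0)
        mask = ndimage.shift(mask, (dy, 0.0), order=0, cval=0)

    # 4. blur (photometric: image only)
    p = config.active("blur")
    if p > 0 and rng.random() < p:
        sigma = rng.uniform(0.5, 1.5)
        image = ndimage.gaussian_filter(image, (sigma, sigma, 0.0))

    # 5. random crop, resized back to the input shape
    p = config.active("random_crop")
    if p > 0 and rng.random() < p:
        f = rng.uniform(0.7, 0.95)
        ch, cw = max(1, int(f * h)), max(1, int(f * w))
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        image, mask = _resize_pair(image[y0 : y0 + ch, x0 : x0 + cw], mask[y0 : y0 + ch, x0 : x0 + cw], (h, w))

    # 6. rotation about the center, zero-filled corners
    p = config.active("random_rotate")
    if p > 0 and rng.random() < p:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        image = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1, cval=0.0)
        mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0, cval=0)

    # 7. zoom in (center crop) or out (zero pad), back to the input shape
    m = config.active("random_resize")
    if m > 0:
        z = 1.0 + rng.uniform(-m, m)
        zh, zw = max(1, int(round(z * h))), max(1, int(round(z * w)))
        image, mask = _resize_pair(image, mask, (zh, zw))
        if zh >= h:
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            image = image[y0 : y0 + h, x0 : x0 + w]
            mask = mask[y0 : y0 + h, x0 : x0 + w]
        else:
            pt, pl = (h - zh) // 2, (w - zw) // 2
            image = np.pad(image, ((pt, h - zh - pt), (pl, w - zw - pl), (0, 0)))
            mask = np.pad(mask, ((pt, h - zh - pt), (pl, w - zw - pl)))

    # 8. flip along a randomly chosen axis
    p = config.active("random_flip")
    if p > 0 and rng.random() < p:
        axis = int(rng.integers(0, 2))
        image = np.flip(image, axis=axis).copy()
        mask = np.flip(mask, axis=axis).copy()

    # 9. multiplicative brightness jitter (image only), clipped to [0, 1]
    m = config.active("random_brightness")
    if m > 0:
        factor = 1.0 + rng.uniform(-m / 2.0, m / 2.0)
        image = np.clip(image * factor, 0.0, 1.0)

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    mask = (mask > 0).astype(np.uint8)
    return ImageRecord(image=image, mask=mask, id=record.id, patient_id=record.patient_id)


def preview_grid(
    record: ImageRecord,
    config: AugmentationConfig,
    n: int,
    seed: int,
    out_path: Union[str, Path],
) -> Path:
    """Write a panel of ``n`` augmented variants with mask-contour overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 2.2 * rows), squeeze=False)
    for i in range(rows * cols):
        ax = axes[i // cols][i % cols]
        ax.axis("off")
        if i >= n:
            continue
        aug = augment_pair(record, config, rng)
        ax.imshow(np.clip(aug.image, 0, 1))
        if aug.mask.any():
            ax.contour(aug.mask, levels=[0.5], colors="red", linewidths=0.8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
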