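"""Loading, preprocessing and splitting of image/mask pairs.

The on-disk layout follows the public LGG MRI collection: each 3-channel
image file (PNG or TIFF) has a sibling single-channel grayscale mask whose
name is the image stem plus a suffix (``_mask`` in the public set).
Preprocessing scales pixels from 0–255 to [0,1], thresholds masks to strict
{0,1}, drops tumor-free images, and splits records 70/20/10 into
train/validation/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image

__all__ = [
    "ImageRecord",
    "DatasetSplit",
    "load_pairs",
    "filter_positive",
    "normalize_global",
    "binarize_mask",
    "preprocess_records",
    "split_dataset",
    "write_split_manifests",
    "DEFAULT_MASK_SUFFIX",
    "DEFAULT_FRACTIONS",
]

DEFAULT_MASK_SUFFIX = "_mask"
DEFAULT_FRACTIONS = (0.7, 0.2, 0.1)
_IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class ImageRecord:
    """One image/mask pair with provenance.

    ``image`` is H×W×3 (raw 0–255 or normalized [0,1]); ``mask`` is H×W and
    strictly {0,1} after preprocessing.  ``id`` is the file stem or a
    synthetic seed tag; ``patient_id`` supports patient-level splitting.
    """

    image: np.ndarray
    mask: np.ndarray
    id: str
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError(
                f"record {self.id!r}: image shape {self.image.shape[:2]} "
                f"!= mask shape {self.mask.shape[:2]}"
            )

    @property
    def is_positive(self) -> bool:
        return bool(np.any(self.mask))


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of a record list."""

    train: List[ImageRecord]
    validation: List[ImageRecord]
    test: List[ImageRecord]
    fractions: Tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = field(default=0)

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def sizes(self) -> Tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


# ---------------------------------------------------------------------------
# loading


def _find_mask_path(image_path: Path, mask_suffix: str) -> Optional[Path]:
    for ext in _IMAGE_EXTENSIONS:
        candidate = image_path.with_name(image_path.stem + mask_suffix + ext)
        if candidate.exists():
            return candidate
    return None


def load_pairs(
    image_dir: Union[str, Path],
    mask_suffix: str = DEFAULT_MASK_SUFFIX,
) -> List[ImageRecord]:
    """Load every image/mask pair under ``image_dir``.

    A file is an image if its stem does not end in ``mask_suffix``; its mask
    shares the stem plus the suffix.  Images without a mask are skipped with
    a warning.  Raises if the directory holds no images at all, or if an
    image and its mask disagree in spatial shape.
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p
        for p in image_dir.iterdir()
        if p.suffix.lower() in _IMAGE_EXTENSIONS and not p.stem.endswith(mask_suffix)
    )
    if not paths:
        raise FileNotFoundError(f"no image files found in {image_dir}")
    records: List[ImageRecord] = []
    for path in paths:
        mask_path = _find_mask_path(path, mask_suffix)
        if mask_path is None:
            warnings.warn(f"no mask found for {path.name}; skipping", stacklevel=2)
            continue
        image = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
        mask = np.asarray(Image.open(mask_path).convert("L"), dtype=np.uint8)
        if image.shape[:2] != mask.shape[:2]:
            raise ValueError(
                f"{path.name}: image shape {image.shape[:2]} does not match "
                f"mask {mask_path.name} shape {mask.shape[:2]}"
            )
        records.append(ImageRecord(image=image, mask=mask, id=path.stem))
    return records


# ---------------------------------------------------------------------------
# preprocessing


def filter_positive(records: Sequence[ImageRecord]) -> List[ImageRecord]:
    """Keep only records whose mask contains at least one foreground pixel.

    This removes tumor-free slices so positive and negative classes do not
    swamp the loss; order is preserved.
    """
    kept = [r for r in records if np.any(r.mask)]
    if not kept:
        warnings.warn("filter_positive removed every record", stacklevel=2)
    return kept


def normalize_global(image: np.ndarray) -> np.ndarray:
    """Scale raw 0–255 pixel values to [0, 1] by elementwise division."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return arr / 255.0


def binarize_mask(mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a normalized grayscale mask: > threshold -> 1 (tumor area)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    arr = np.asarray(mask, dtype=np.float32)
    return (arr > threshold).astype(np.uint8)


def preprocess_records(
    records: Sequence[ImageRecord],
    threshold: float = 0.5,
    drop_negative: bool = True,
) -> List[ImageRecord]:
    """Normalize images, binarize masks, and (optionally) drop tumor-free slices.

    Masks stored on the raw 0–255 grayscale scale are rescaled before
    thresholding; masks already in [0, 1] are thresholded directly.
    """
    out = []
    for r in records:
        mask = np.asarray(r.mask, dtype=np.float32)
        if mask.max() > 1.0:
            mask = normalize_global(mask)
        out.append(
            ImageRecord(
                image=normalize_global(r.image),
                mask=binarize_mask(mask, threshold),
                id=r.id,
                patient_id=r.patient_id,
            )
        )
    return filter_positive(out) if drop_negative else out


# ---------------------------------------------------------------------------
# splitting


def _partition_sizes(n: int, fractions: Tuple[float, float, float]) -> Tuple[int, int, int]:
    # validation/test get round(n*f); the remainder goes to train (the
    # largest partition) so sizes are deterministic and exhaustive.
    n_val = round(n * fractions[1])
    n_test = round(n * fractions[2])
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError(f"fractions {fractions} over-allocate {n} records")
    return n_train, n_val, n_test


def split_dataset(
    records: Sequence[ImageRecord],
    fractions: Tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    by_patient: bool = False,
) -> DatasetSplit:
    """Randomly partition records into train/validation/test.

    Deterministic for a given seed; partitions are disjoint and exhaustive.
    With ``by_patient`` whole patient groups are assigned to one partition
    (prevents leakage of a patient's slices across splits; records lacking a
    ``patient_id`` each form their own group).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = _partition_sizes(n, fractions)

    if by_patient:
        # whole patient groups go to one partition; sizes approximate the
        # fractions (test filled first, then validation, remainder to train)
        groups: dict = {}
        for i, r in enumerate(records):
            key = r.patient_id if r.patient_id is not None else f"__solo_{i}"
            groups.setdefault(key, []).append(i)
        keys = sorted(groups)
        rng.shuffle(keys)
        idx_train, idx_val, idx_test = [], [], []
        for k in keys:
            if len(idx_test) < n_test:
                idx_test.extend(groups[k])
            elif len(idx_val) < n_val:
                idx_val.extend(groups[k])
            else:
                idx_train.extend(groups[k])
    else:
        order = list(rng.permutation(n))
        idx_train = order[:n_train]
        idx_val = order[n_train : n_train + n_val]
        idx_test = order[n_train + n_val :]
    return DatasetSplit(
        train=[records[i] for i in idx_train],
        validation=[records[i] for i in idx_val],
        test=[records[i] for i in idx_test],
        fractions=tuple(fractions),
        seed=seed,
    )


def write_split_manifests(split: DatasetSplit, out_dir: Union[str, Path]) -> List[Path]:
    """Write one plain-text file list per partition (one record id per line)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, part in zip(("train", "validation", "test"), split):
        path = out_dir / f"{name}.txt"
        path.write_text("".join(f"{r.id}\n" for r in part))
        written.append(path)
    return written
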