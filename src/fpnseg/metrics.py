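"""Overlap metrics and the smoothed Dice loss for binary segmentation.

Conventions
-----------
A is the predicted pixel set, B the reference (ground-truth) set.  The
evaluation metrics (``dsc``, ``jaccard``, ``pixel_accuracy``) operate on
hard {0,1} masks; ``dice_loss`` additionally accepts soft probability maps,
in which case |A ∩ B| is the sum of elementwise products and |A| the sum of
predicted probabilities — the standard continuous relaxation used to make
the loss differentiable.

The smoothing constant xi (default 100) keeps the loss defined when both
masks are empty: (0 + xi)/(0 + xi) = 1, so the loss is 0 rather than 0/0.
For the unsmoothed metrics, both-masks-empty is defined as perfect
agreement (1.0).
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple, Union

import numpy as np

__all__ = [
    "ConfusionCounts",
    "dice_loss",
    "dsc",
    "jaccard",
    "confusion_counts",
    "pixel_accuracy",
    "score_mask_files",
    "DEFAULT_SMOOTHING",
]

DEFAULT_SMOOTHING = 100.0


class ConfusionCounts(NamedTuple):
    """Pixelwise confusion tallies: label/prediction 1/1, 0/0, 0/1, 1/0."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_pair(predicted: np.ndarray, reference: np.ndarray, hard: bool) -> tuple:
    p = np.asarray(predicted, dtype=np.float64)
    g = np.asarray(reference, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: predicted {p.shape} vs reference {g.shape}")
    if not np.isin(np.unique(g), (0.0, 1.0)).all():
        raise ValueError("reference mask must be strictly binary")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("predicted values must lie in [0, 1]")
    if hard and not np.isin(np.unique(p), (0.0, 1.0)).all():
        raise ValueError("predicted mask must be strictly binary for this metric")
    return p, g


def dice_loss(
    predicted: np.ndarray,
    reference: np.ndarray,
    xi: float = DEFAULT_SMOOTHING,
) -> float:
    """Smoothed Dice loss: 1 - (2|A∩B| + xi) / (|A| + |B| + xi).

    ``predicted`` may be soft (probabilities in [0,1]) or hard binary;
    ``reference`` must be binary.  ``xi >= 0`` is the smoothing term that
    prevents a zero denominator.
    """
    if xi < 0:
        raise ValueError(f"xi must be >= 0, got {xi}")
    p, g = _check_pair(predicted, reference, hard=False)
    inter = float((p * g).sum())
    den = float(p.sum()) + float(g.sum()) + xi
    if den == 0.0:  # xi = 0 and both masks empty: perfect agreement
        return 0.0
    return 1.0 - (2.0 * inter + xi) / den


def dsc(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) on hard masks."""
    p, g = _check_pair(predicted, reference, hard=True)
    den = float(p.sum()) + float(g.sum())
    if den == 0.0:
        return 1.0
    return 2.0 * float((p * g).sum()) / den


def jaccard(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Jaccard / IoU index |A∩B| / (|A| + |B| - |A∩B|) on hard masks."""
    p, g = _check_pair(predicted, reference, hard=True)
    inter = float((p * g).sum())
    union = float(p.sum()) + float(g.sum()) - inter
    if union == 0.0:
        return 1.0
    return inter / union


def confusion_counts(predicted: np.ndarray, reference: np.ndarray) -> ConfusionCounts:
    """Exhaustive per-pixel TP/TN/FP/FN tally over a hard binary pair."""
    p, g = _check_pair(predicted, reference, hard=True)
    pb = p.astype(bool)
    gb = g.astype(bool)
    tp = int(np.count_nonzero(pb & gb))
    tn = int(np.count_nonzero(~pb & ~gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """Acc = (TP + TN) / (TP + TN + FN + FP)."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    return (counts.tp + counts.tn) / counts.total


def score_mask_files(
    predicted_path: Union[str, Path],
    reference_path: Union[str, Path],
    threshold: float = 0.5,
) -> dict:
    """Standalone scoring entry point over two single-channel mask PNGs.

    Both files are read as grayscale, scaled to [0,1] and binarised at
    ``threshold``; returns {"dsc": ..., "jaccard": ..., "accuracy": ...}.
    """
    from PIL import Image

    def _load(path: Union[str, Path]) -> np.ndarray:
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
        return (arr > threshold).astype(np.uint8)

    pred = _load(predicted_path)
    ref = _load(reference_path)
    counts = confusion_counts(pred, ref)
    return {
        "dsc": dsc(pred, ref),
        "jaccard": jaccard(pred, ref),
        "accuracy": pixel_accuracy(counts),
    }
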