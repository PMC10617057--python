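"""Training and evaluation harness.

The protocol: minibatch Adam (default batch 8, learning rate 1e-4) on the
smoothed Dice loss, up to 150 epochs with early stopping on the validation
Dice loss (patience 10 epochs, min_delta 1e-4) and restoration of the best
weights.  Augmentation is applied to training batches only; validation and
test passes run the model in inference mode without augmentation.

Evaluation reports the per-image means of DSC and Jaccard plus the global
pixel accuracy (accuracy pooled over all pixels), alongside a per-image
table for inspection; per-image vs pooled DSC aggregation is switchable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import metrics
from .augment import AugmentationConfig, augment_pair
from .data import DatasetSplit, ImageRecord
from .models import ModelConfig, Module, build_model, forward_batch, predict_mask
from .nn import Adam, Tensor
from .nn import functional as F

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "EarlyStopper",
    "train",
    "evaluate",
    "EvaluationReport",
    "compare_models",
    "overfit_single_batch",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters (defaults follow the study protocol)."""

    batch_size: int = 8
    max_epochs: int = 150
    learning_rate: float = 1e-4
    xi: float = metrics.DEFAULT_SMOOTHING
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    bce_weight: float = 0.0  # optional compound Dice + BCE loss; off by default
    per_image_loss: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch loss/metric trajectory and the early-stopping outcome."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_dsc: List[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "val_dsc"])
            for i, row in enumerate(zip(self.train_loss, self.val_loss, self.val_dsc), 1):
                writer.writerow([i, *row])
        return path


class EarlyStopper:
    """Stop when the monitored loss fails to improve by min_delta for `patience` epochs."""

    def __init__(self, patience: int, min_delta: float):
        self.patience = patience
        self.min_delta = min_delta
        self.best: float = np.inf
        self.best_epoch: int = 0
        self._since_best = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record an epoch's monitor value; returns True if training should stop."""
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


def _to_batch(records: Sequence[ImageRecord]) -> Tuple[np.ndarray, np.ndarray]:
    images = np.stack([np.asarray(r.image, np.float32).transpose(2, 0, 1) for r in records])
    masks = np.stack([np.asarray(r.mask, np.float32)[None] for r in records])
    return images, masks


def _loss(model_out: Tensor, masks: np.ndarray, config: TrainingConfig) -> Tensor:
    loss = F.soft_dice_loss(model_out, masks, xi=config.xi, per_image=config.per_image_loss)
    if config.bce_weight > 0:
        bce = F.bce_loss(model_out, masks)
        loss = Tensor(
            loss.data + config.bce_weight * bce.data,
            parents=(loss, bce),
            backward=lambda g: (loss.accumulate(g), bce.accumulate(config.bce_weight * g)),
        )
    return loss


def _validation_pass(
    model: Module, records: Sequence[ImageRecord], config: TrainingConfig
) -> Tuple[float, float]:
    """(mean validation dice loss, mean per-image DSC) without augmentation."""
    model.eval()
    losses, dscs = [], []
    for start in range(0, len(records), config.batch_size):
        chunk = records[start : start + config.batch_size]
        images, masks = _to_batch(chunk)
        out = model(Tensor(images))
        losses.append(F.soft_dice_loss(out, masks, xi=config.xi).item())
        for probs, rec in zip(out.data[:, 0], chunk):
            dscs.append(metrics.dsc(predict_mask(probs), rec.mask))
    model.train()
    return float(np.mean(losses)), float(np.mean(dscs))


def train(
    model: Module,
    split: DatasetSplit,
    tconfig: Optional[TrainingConfig] = None,
    aconfig: Optional[AugmentationConfig] = None,
    verbose: bool = False,
) -> Tuple[Dict[str, np.ndarray], TrainingHistory]:
    """Train ``model`` on ``split.train``, early-stopping on ``split.validation``.

    Augmentation (if configured) touches training batches only.  On stop the
    best-epoch weights are restored into the model and also returned as a
    state dict.  Fully deterministic for a fixed seed.
    """
    tconfig = tconfig or TrainingConfig()
    aconfig = aconfig if aconfig is not None else AugmentationConfig()
    if not split.train or not split.validation:
        raise ValueError("train and validation partitions must be non-empty")

    rng = np.random.default_rng(tconfig.seed)
    optimizer = Adam(model.parameters(), lr=tconfig.learning_rate)
    stopper = EarlyStopper(tconfig.patience, tconfig.min_delta)
    history = TrainingHistory()
    best_state = model.state_dict()
    model.train()

    for epoch in range(1, tconfig.max_epochs + 1):
        order = rng.permutation(len(split.train))
        epoch_losses = []
        for start in range(0, len(order), tconfig.batch_size):
            batch = [split.train[i] for i in order[start : start + tconfig.batch_size]]
            if aconfig.enabled:
                batch = [augment_pair(r, aconfig, rng) for r in batch]
            images, masks = _to_batch(batch)
            out = model(Tensor(images))
            loss = _loss(out, masks, tconfig)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())

        val_loss, val_dsc = _validation_pass(model, split.validation, tconfig)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_dsc.append(val_dsc)
        if verbose:
            print(
                f"epoch {epoch:3d}  train_loss {history.train_loss[-1]:.4f}  "
                f"val_loss {val_loss:.4f}  val_dsc {val_dsc:.4f}"
            )
        improved_to_best = val_loss < stopper.best - stopper.min_delta
        should_stop = stopper.update(epoch, val_loss)
        if improved_to_best:
            best_state = model.state_dict()
        if should_stop:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = tconfig.max_epochs
    history.best_epoch = stopper.best_epoch or history.stopped_epoch
    model.load_state_dict(best_state)
    model.eval()
    return best_state, history


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationReport:
    """Aggregate metrics plus the per-image table behind them."""

    dsc_mean: float
    jaccard_mean: float
    accuracy: float
    dsc_pooled: float
    jaccard_pooled: float
    per_image: pd.DataFrame

    def summary(self, name: str = "model") -> str:
        return (
            f"{name}: DSC {self.dsc_mean:.4f}  Jaccard {self.jaccard_mean:.4f}  "
            f"accuracy {self.accuracy:.4f}  (n={len(self.per_image)})"
        )


def evaluate(
    model: Module,
    records: Sequence[ImageRecord],
    threshold: float = 0.5,
    batch_size: int = 8,
) -> EvaluationReport:
    """Score a model on preprocessed records.

    DSC/Jaccard are reported as per-image means (pooled-over-all-pixels
    variants are included alongside); accuracy is the global pixel ratio.
    """
    if not records:
        raise ValueError("no records to evaluate")
    model.eval()
    rows = []
    totals = metrics.ConfusionCounts(0, 0, 0, 0)
    pooled_inter = pooled_pred = pooled_ref = 0.0
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        images = np.stack([np.asarray(r.image, np.float32) for r in chunk])
        probs = forward_batch(model, images)
        for pm, rec in zip(probs, chunk):
            pred = predict_mask(pm, threshold)
            counts = metrics.confusion_counts(pred, rec.mask)
            totals = metrics.ConfusionCounts(*(a + b for a, b in zip(totals, counts)))
            pooled_inter += counts.tp
            pooled_pred += counts.tp + counts.fp
            pooled_ref += counts.tp + counts.fn
            rows.append(
                {
                    "id": rec.id,
                    "dsc": metrics.dsc(pred, rec.mask),
                    "jaccard": metrics.jaccard(pred, rec.mask),
                    "accuracy": metrics.pixel_accuracy(counts),
                }
            )
    table = pd.DataFrame(rows)
    den = pooled_pred + pooled_ref
    dsc_pooled = 1.0 if den == 0 else 2.0 * pooled_inter / den
    union = den - pooled_inter
    jac_pooled = 1.0 if union == 0 else pooled_inter / union
    return EvaluationReport(
        dsc_mean=float(table["dsc"].mean()),
        jaccard_mean=float(table["jaccard"].mean()),
        accuracy=metrics.pixel_accuracy(totals),
        dsc_pooled=float(dsc_pooled),
        jaccard_pooled=float(jac_pooled),
        per_image=table,
    )


def compare_models(
    split: DatasetSplit,
    model_kinds: Sequence[str],
    mconfig: ModelConfig,
    tconfig: Optional[TrainingConfig] = None,
    aconfig: Optional[AugmentationConfig] = None,
    threshold: float = 0.5,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train each model under identical settings and tabulate test metrics.

    Returns one row per model with DSC / Jaccard / accuracy columns, the
    shape of a model-comparison table.
    """
    if len(model_kinds) < 2:
        raise ValueError("need at least two model kinds to compare")
    rows = []
    for kind in model_kinds:
        model = build_model(kind, mconfig)
        _, history = train(model, split, tconfig, aconfig, verbose=verbose)
        report = evaluate(model, split.test, threshold=threshold)
        rows.append(
            {
                "model": kind,
                "dsc": report.dsc_mean,
                "jaccard": report.jaccard_mean,
                "accuracy": report.accuracy,
                "best_epoch": history.best_epoch,
                "stopped_epoch": history.stopped_epoch,
            }
        )
    return pd.DataFrame(rows)


def overfit_single_batch(
    model: Module,
    records: Sequence[ImageRecord],
    steps: int = 200,
    learning_rate: float = 1e-4,
    xi: float = metrics.DEFAULT_SMOOTHING,
    threshold: float = 0.5,
) -> float:
    """Adam-optimize on one fixed batch; returns the final training DSC.

    A sanity probe of the optimisation path: a healthy network memorizes a
    single batch almost perfectly.
    """
    images, masks = _to_batch(records)
    optimizer = Adam(model.parameters(), lr=learning_rate)
    model.train()
    for _ in range(steps):
        out = model(Tensor(images))
        loss = F.soft_dice_loss(out, masks, xi=xi)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    model.eval()
    out = model(Tensor(images))
    pred = predict_mask(out.data, threshold)
    return metrics.dsc(pred, masks.astype(np.uint8))
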