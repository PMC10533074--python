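"""Segmentation losses and metrics.

For binary masks X (ground truth) and Y (prediction) the suite computes the
pixel confusion counts and

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PRE = TP / (TP + FP)
    REC = TP / (TP + FN)
    DSC = 2|X ∩ Y| / (|X| + |Y|)      = 2 TP / (2 TP + FP + FN)
    IoU = |X ∩ Y| / |X ∪ Y|           = TP / (TP + FP + FN)

plus the pixel-wise ROC AUC on raw probabilities.  The training loss is the
soft Dice loss 1 − (2|X ∩ Y| + ε) / (|X| + |Y| + ε) with smoothing ε = 1 by
default; the metric DSC itself is reported unsmoothed.  Degenerate
denominators yield 0.0 (1.0 for DSC/IoU when both masks are empty; 0.5 for
AUC on single-class truth), each with a RuntimeWarning rather than an
exception, so all-background validation tiles do not abort a run.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ShapeError

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "confusion_counts",
    "accuracy",
    "precision",
    "recall",
    "dice_coefficient",
    "iou",
    "dice_loss",
    "auc_pixelwise",
    "evaluate_image",
    "evaluate_batch",
    "write_report",
]

DEFAULT_SMOOTH = 1.0
THRESHOLD = 0.5


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class SegmentationMetrics:
    acc: float
    pre: float
    rec: float
    dsc: float
    iou: float
    auc: float


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return pred >= THRESHOLD if pred.dtype.kind == "f" else pred.astype(bool), truth.astype(bool)


def confusion_counts(pred_mask, truth_mask) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/TN/FN between two binary masks."""
    p, t = _check_binary_pair(pred_mask, truth_mask)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning 0.0", RuntimeWarning)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def dice_coefficient(pred_mask, truth_mask) -> float:
    """DSC between binary masks; 1.0 when both masks are empty."""
    p, t = _check_binary_pair(pred_mask, truth_mask)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & t)) / denom


def iou(pred_mask, truth_mask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    p, t = _check_binary_pair(pred_mask, truth_mask)
    union = int(np.sum(p | t))
    if union == 0:
        return 1.0
    return int(np.sum(p & t)) / union


def dice_loss(pred_prob, truth, smooth: float = DEFAULT_SMOOTH) -> float:
    """Soft Dice loss 1 − (2 Σ p·y + ε) / (Σ p + Σ y + ε)."""
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"shapes differ: {p.shape} vs {y.shape}")
    inter = float((p * y).sum())
    return 1.0 - (2.0 * inter + smooth) / (float(p.sum() + y.sum()) + smooth)


def auc_pixelwise(pred_prob, truth) -> float:
    """ROC AUC over flattened pixels (Mann-Whitney statistic).

    Returns 0.5 with a warning when the truth contains a single class."""
    p = np.asarray(pred_prob, dtype=np.float64).ravel()
    t = np.asarray(truth).ravel().astype(int)
    if p.shape != t.shape:
        raise ShapeError("probability map and mask sizes differ")
    if t.min() == t.max():
        warnings.warn("AUC undefined for single-class truth; returning 0.5", RuntimeWarning)
        return 0.5
    return float(roc_auc_score(t, p))


def evaluate_image(pred_prob, truth_mask, threshold: float = THRESHOLD) -> SegmentationMetrics:
    """All metrics for one probability map against one binary mask."""
    pred_prob = np.asarray(pred_prob)
    truth_mask = np.asarray(truth_mask)
    pred_bin = pred_prob >= threshold
    c = confusion_counts(pred_bin, truth_mask)
    return SegmentationMetrics(
        acc=accuracy(c),
        pre=precision(c),
        rec=recall(c),
        dsc=dice_coefficient(pred_bin, truth_mask),
        iou=iou(pred_bin, truth_mask),
        auc=auc_pixelwise(pred_prob, truth_mask),
    )


def evaluate_batch(
    pred_probs: Sequence[np.ndarray],
    truth_masks: Sequence[np.ndarray],
    names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-image metric rows plus a final ``mean`` row (AUC pooled per image,
    averaged over images)."""
    if len(pred_probs) != len(truth_masks):
        raise ShapeError("number of predictions and masks differ")
    names = list(names) if names is not None else [f"img_{i:03d}" for i in range(len(pred_probs))]
    rows = []
    for name, p, t in zip(names, pred_probs, truth_masks):
        m = evaluate_image(p, t)
        rows.append({"image": name, **dataclasses.asdict(m)})
    df = pd.DataFrame(rows)
    mean_row = {"image": "mean", **df[["acc", "pre", "rec", "dsc", "iou", "auc"]].mean().to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def write_report(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
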