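"""Segmentation-overlap and score-agreement metrics.

Overlap between a predicted and a reference vessel mask is summarised by
voxel confusion counts, from which IOU = TP/(TP+FP+FN) and
Dice = 2TP/(2TP+FP+FN) follow.  Agreement between automated and manual
calcium scores is summarised by (mean) absolute percentage error and by an
ordinary least-squares line with its coefficient of determination
r² = 1 − RSS/TSS.  Binary cross-entropy is provided for training
diagnostics.

Per-patient segmentation accuracy is always the mean of per-slice Dice
scores, never pooled-voxel Dice.  A slice on which both masks are empty
scores Dice = IOU = 1 (perfect agreement on absence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume import BinaryMask

__all__ = [
    "ConfusionCounts",
    "RegressionSummary",
    "confusion",
    "iou",
    "dice",
    "mape",
    "ape",
    "r_squared",
    "fit_line",
    "bce",
    "per_slice_dice",
    "mean_slice_dice",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise true/false positive/negative counts for a mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RegressionSummary:
    """Ordinary least-squares line y = slope·x + intercept with its r²."""

    slope: float
    intercept: float
    r_squared: float


def _as_binary(a) -> np.ndarray:
    if isinstance(a, BinaryMask):
        return a.voxels
    a = np.asarray(a)
    if not np.all(np.isin(np.unique(a), (0, 1))):
        raise ValueError("mask values must be in {0, 1}")
    return a.astype(np.uint8)


def confusion(pred, truth) -> ConfusionCounts:
    """Voxelwise confusion counts between predicted and reference masks."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    pb = p.astype(bool)
    tb = t.astype(bool)
    tp = int(np.count_nonzero(pb & tb))
    fp = int(np.count_nonzero(pb & ~tb))
    fn = int(np.count_nonzero(~pb & tb))
    tn = int(np.count_nonzero(~pb & ~tb))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(c: ConfusionCounts) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def dice(c: ConfusionCounts) -> float:
    """Dice score 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def ape(y_true: float, y_pred: float) -> float:
    """Absolute percentage error |y_true − y_pred| / y_true × 100."""
    y_true = float(y_true)
    if y_true == 0:
        raise ZeroDivisionError("APE is undefined for a zero reference value")
    return abs(y_true - float(y_pred)) / abs(y_true) * 100.0


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error over paired samples, in percent."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if np.any(yt == 0):
        raise ZeroDivisionError("MAPE is undefined when any reference value is zero")
    return float(np.mean(np.abs(yt - yp) / np.abs(yt)) * 100.0)


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 − RSS/TSS of predictions vs truth."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("need at least two paired samples")
    tss = float(np.sum((yt - yt.mean()) ** 2))
    if tss == 0:
        raise ZeroDivisionError("r² undefined: reference values are constant (TSS = 0)")
    rss = float(np.sum((yt - yp) ** 2))
    return 1.0 - rss / tss


def fit_line(x, y) -> RegressionSummary:
    """Least-squares line through (x, y) with intercept, and its r²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least two paired samples")
    res = stats.linregress(x, y)
    return RegressionSummary(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def bce(y_true, y_prob, clamp: float = 1e-7) -> float:
    """Mean binary cross-entropy with probabilities clamped to [ε, 1−ε]."""
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(y_prob, dtype=float), clamp, 1.0 - clamp)
    if y.shape != p.shape:
        raise ValueError("shape mismatch")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def per_slice_dice(pred, truth) -> np.ndarray:
    """Dice score of each transverse slice, pred vs reference."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    return np.array([dice(confusion(p[i], t[i])) for i in range(p.shape[0])])


def mean_slice_dice(pred, truth) -> float:
    """Per-patient accuracy: per-slice Dice averaged across all slices."""
    return float(per_slice_dice(pred, truth).mean())
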