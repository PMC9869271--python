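"""Pixel-level segmentation metrics and counting agreement.

Everything derives from the binary confusion matrix between a predicted
mask and its reference: with gland pixels as the positive class,

    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)
    mIoU      = ( TP/(TP+FP+FN) + TN/(TN+FN+FP) ) / 2

i.e. mean intersection-over-union averages the gland-class IoU with the
background-class IoU (for which TN plays the role of true positives).
Counting agreement between predicted and reference per-tile counts is the
squared Pearson correlation coefficient (r^2).

Degenerate ratios (empty denominator, e.g. a prediction with no positive
pixels at all) are reported as NaN and flagged, not silently clamped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "segmentation_metrics",
    "count_r2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary prediction against its reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricReport:
    miou: float
    precision: float
    recall: float
    f1: float
    pixel_accuracy: float
    iou_foreground: float
    iou_background: float

    @property
    def degenerate(self) -> bool:
        return any(math.isnan(v) for v in asdict(self).values())

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def confusion(pred: np.ndarray, label: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN pixels between two binary masks of equal shape."""
    pred = np.asarray(pred)
    label = np.asarray(label)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    for name, arr in (("pred", pred), ("label", label)):
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    p = pred.astype(bool)
    l = label.astype(bool)
    tp = int(np.count_nonzero(p & l))
    fp = int(np.count_nonzero(p & ~l))
    fn = int(np.count_nonzero(~p & l))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=p.size - tp - fp - fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def segmentation_metrics(c: ConfusionCounts) -> MetricReport:
    """Compute the report of precision, recall, F1, per-class IoU and mIoU."""
    iou_fg = _ratio(c.tp, c.tp + c.fp + c.fn)
    iou_bg = _ratio(c.tn, c.tn + c.fn + c.fp)
    return MetricReport(
        miou=(iou_fg + iou_bg) / 2.0,
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        pixel_accuracy=_ratio(c.tp + c.tn, c.total),
        iou_foreground=iou_fg,
        iou_background=iou_bg,
    )


def count_r2(pred_counts, ref_counts) -> float:
    """Squared Pearson correlation between predicted and reference counts."""
    pred = np.asarray(pred_counts, dtype=float)
    ref = np.asarray(ref_counts, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("count vectors must be 1-d and of equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 paired counts")
    for name, v in (("pred_counts", pred), ("ref_counts", ref)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} has zero variance; r^2 undefined")
    r = stats.pearsonr(pred, ref).statistic
    return float(r * r)
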