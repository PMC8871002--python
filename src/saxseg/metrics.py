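"""Segmentation evaluation: confusion counts, overlap ratios, boundary F1.

All ratio metrics derive from one-vs-rest counts of an accumulated C x C
confusion matrix (rows = truth, cols = prediction).  Undefined 0/0 ratios
follow one convention throughout: 1 when the class is absent from both
masks, 0 otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "MetricAccumulator",
    "confusion_matrix",
    "binary_counts",
    "segmentation_metrics",
    "dataset_metrics",
    "bf_score",
    "mean_bf_score",
    "default_bf_tolerance",
    "class_boundary",
]

RATIO_METRICS = ("dice", "jaccard", "sensitivity", "specificity", "ppv", "npv")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"true_{c}" for c in range(self.num_classes)]
        cols = [f"pred_{c}" for c in range(self.num_classes)]
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> ConfusionMatrix:
    """counts[t][p] = number of pixels with truth t and prediction p."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    for name, a in (("pred", pred), ("truth", truth)):
        if a.size and (a.min() < 0 or a.max() >= num_classes):
            raise ValueError(f"{name} contains classes outside [0, {num_classes})")
    flat = truth.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64)
    counts = np.bincount(flat, minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def binary_counts(cm: ConfusionMatrix, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class ``c``."""
    if not 0 <= c < cm.num_classes:
        raise ValueError(f"class {c} outside [0, {cm.num_classes})")
    m = cm.counts
    tp = int(m[c, c])
    fp = int(m[:, c].sum()) - tp
    fn = int(m[c, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _ratio(num: float, den: float, absent_both: bool) -> float:
    if den == 0:
        return 1.0 if absent_both else 0.0
    return num / den


@dataclass
class MetricReport:
    """Per-class and aggregate values of every reported metric.

    Aggregates of the ratio metrics are unweighted means over the
    foreground classes (all classes except 0); per-class vectors are kept
    alongside.
    """

    per_class: dict[str, np.ndarray]
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_bf_score: float | None = None
    aggregates: dict[str, float] = field(default_factory=dict)

    def __getattr__(self, name: str):
        aggr = self.__dict__.get("aggregates", {})
        if name in aggr:
            return aggr[name]
        raise AttributeError(name)

    @property
    def mean_dice(self) -> float:
        return self.aggregates["dice"]

    def to_dict(self) -> dict:
        out = {
            "per_class": {k: [float(x) for x in v] for k, v in self.per_class.items()},
            "global_accuracy": self.global_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "mean_iou": self.mean_iou,
            "weighted_iou": self.weighted_iou,
        }
        out.update({k: float(v) for k, v in self.aggregates.items()})
        if self.mean_bf_score is not None:
            out["mean_bf_score"] = float(self.mean_bf_score)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class)


def segmentation_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All confusion-derived metrics of the report tables."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    C = cm.num_classes
    per: dict[str, list[float]] = {k: [] for k in RATIO_METRICS}
    for c in range(C):
        tp, fp, fn, tn = binary_counts(cm, c)
        absent = (tp + fn == 0) and (tp + fp == 0)  # class in neither mask
        per["dice"].append(_ratio(2 * tp, 2 * tp + fp + fn, absent))
        per["jaccard"].append(_ratio(tp, tp + fp + fn, absent))
        per["sensitivity"].append(_ratio(tp, tp + fn, absent))
        per["specificity"].append(_ratio(tn, tn + fp, absent))
        per["ppv"].append(_ratio(tp, tp + fp, absent))
        per["npv"].append(_ratio(tn, tn + fn, absent))
    per_class = {k: np.asarray(v) for k, v in per.items()}
    fg = slice(1, C) if C > 1 else slice(0, C)
    aggregates = {k: float(v[fg].mean()) for k, v in per_class.items()}
    ga, ma, mi, wi = dataset_metrics(cm)
    return MetricReport(
        per_class=per_class,
        global_accuracy=ga,
        mean_accuracy=ma,
        mean_iou=mi,
        weighted_iou=wi,
        aggregates=aggregates,
    )


def dataset_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(global accuracy, mean accuracy, mean IoU, weighted IoU)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    C = cm.num_classes
    recalls, ious, shares = [], [], []
    for c in range(C):
        tp, fp, fn, tn = binary_counts(cm, c)
        absent = (tp + fn == 0) and (tp + fp == 0)
        recalls.append(_ratio(tp, tp + fn, absent))
        ious.append(_ratio(tp, tp + fp + fn, absent))
        shares.append((tp + fn) / cm.total)
    global_acc = float(np.trace(cm.counts) / cm.total)
    weighted_iou = float(sum(s * i for s, i in zip(shares, ious)))
    return global_acc, float(np.mean(recalls)), float(np.mean(ious)), weighted_iou


def default_bf_tolerance(shape: tuple[int, int]) -> int:
    """0.75% of the image diagonal, rounded up."""
    return math.ceil(0.0075 * math.hypot(*shape))


_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def class_boundary(mask: np.ndarray, c: int) -> np.ndarray:
    """Boolean map of class-c pixels with a 4-neighbor (or image edge) outside c."""
    region = np.asarray(mask) == c
    if not region.any():
        return np.zeros_like(region)
    interior = ndimage.binary_erosion(region, structure=_FOUR_CONN, border_value=0)
    return region & ~interior


def bf_score(
    pred: np.ndarray,
    truth: np.ndarray,
    c: int,
    tolerance: float | None = None,
) -> float:
    """Boundary F1 for class ``c``: harmonic mean of boundary precision/recall.

    A boundary pixel counts as matched when it lies within ``tolerance``
    (Euclidean) of any boundary pixel of the other mask.  A class absent
    from both masks scores 1; absent from exactly one, 0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if tolerance is None:
        tolerance = default_bf_tolerance(pred.shape)
    bp = class_boundary(pred, c)
    bt = class_boundary(truth, c)
    if not bp.any() and not bt.any():
        return 1.0
    if not bp.any() or not bt.any():
        return 0.0
    dist_to_truth = ndimage.distance_transform_edt(~bt)
    dist_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float((dist_to_truth[bp] <= tolerance).mean())
    recall = float((dist_to_pred[bt] <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mean_bf_score(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    num_classes: int,
    tolerance: float | None = None,
    foreground_only: bool = True,
) -> float:
    """Mean BF score over slices and (by default foreground) classes."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equally many non-empty pred and truth collections")
    classes = range(1, num_classes) if foreground_only and num_classes > 1 else range(num_classes)
    scores = [
        bf_score(p, t, c, tolerance) for p, t in zip(preds, truths) for c in classes
    ]
    return float(np.mean(scores))


class MetricAccumulator:
    """Accumulates the confusion matrix (micro) and per-slice BF scores."""

    def __init__(self, num_classes: int, tolerance: float | None = None):
        self.num_classes = num_classes
        self.tolerance = tolerance
        self.cm = ConfusionMatrix(np.zeros((num_classes, num_classes), dtype=np.int64))
        self._bf: list[float] = []

    def add(self, pred: np.ndarray, truth: np.ndarray) -> None:
        self.cm = self.cm + confusion_matrix(pred, truth, self.num_classes)
        classes = range(1, self.num_classes) if self.num_classes > 1 else [0]
        for c in classes:
            self._bf.append(bf_score(pred, truth, c, self.tolerance))

    def report(self) -> MetricReport:
        rep = segmentation_metrics(self.cm)
        rep.mean_bf_score = float(np.mean(self._bf)) if self._bf else None
        return rep
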