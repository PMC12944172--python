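"""Polygon-level confusion matrix and detection metrics.

Two deliberately distinct matching regimes coexist here:

* The confusion matrix is *reference-polygon-centric* and uses plain
  polygon-box intersection (positive interior overlap). A "White Pine"
  reference polygon intersecting at least one detection box is a TP,
  otherwise an FN; an "Other" polygon intersecting at least one box is an
  FP, otherwise a TN. Matrix row sums therefore equal the reference-layer
  sizes, which is what makes the map-based tables reconstructible. A single
  detection may contribute to several reference polygons, and several
  detections on one polygon count once.

* Average precision uses classic IoU matching: detections sorted by
  descending confidence are greedily assigned one-to-one to reference
  boxes at IoU >= threshold (0.5 by default), and AP is the area under the
  all-points-interpolated precision-recall curve.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), OA = (TP+TN)/(TP+FP+FN+TN).
Undefined ratios (zero denominators) are reported as NaN, never as 0.
Reported metrics are rounded half-up to 2 decimals at the reporting layer
only; raw ratios are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import Polygon

from .geometry import BBox, iou
from .postprocess import Detection

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ApResult",
    "assign_outcomes",
    "compute_metrics",
    "average_precision",
    "round_half_up",
    "format_confusion_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 polygon-level tally; the assessment unit is a reference polygon."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_target(self) -> int:
        """Number of target-class ('White Pine') reference polygons."""
        return self.tp + self.fn

    @property
    def n_other(self) -> int:
        """Number of non-target ('Other') reference polygons."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    overall_accuracy: float

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        return MetricSet(
            round_half_up(self.precision, ndigits),
            round_half_up(self.recall, ndigits),
            round_half_up(self.overall_accuracy, ndigits),
        )


@dataclass(frozen=True)
class ApResult:
    average_precision: float
    iou_threshold: float
    precision: np.ndarray
    recall: np.ndarray


def round_half_up(x: float, ndigits: int = 2) -> float:
    if np.isnan(x):
        return float("nan")
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _hit_flags(polys: Sequence[Polygon], boxes: list[Polygon]) -> np.ndarray:
    """Boolean per reference polygon: positive-area overlap with any box."""
    flags = np.zeros(len(polys), dtype=bool)
    if not boxes or not polys:
        return flags
    tree = STRtree(boxes)
    for i, p in enumerate(polys):
        for j in tree.query(p, predicate="intersects"):
            if p.intersection(boxes[j]).area > 0.0:
                flags[i] = True
                break
    return flags


def assign_outcomes(
    crowns: Sequence[Polygon],
    others: Sequence[Polygon],
    dets: Sequence[Detection],
) -> ConfusionMatrix:
    """Classify every reference polygon by intersection with detections.

    Expects post-processed detections (already thresholded / NMS'd); this
    function applies no filtering of its own.
    """
    boxes = [d.box.to_shapely() for d in dets]
    crown_hit = _hit_flags(crowns, boxes)
    other_hit = _hit_flags(others, boxes)
    return ConfusionMatrix(
        tp=int(crown_hit.sum()),
        fn=int(len(crowns) - crown_hit.sum()),
        fp=int(other_hit.sum()),
        tn=int(len(others) - other_hit.sum()),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else float("nan")
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    oa = (cm.tp + cm.tn) / cm.total
    return MetricSet(precision=precision, recall=recall, overall_accuracy=oa)


def average_precision(
    dets: Sequence[Detection],
    reference_boxes: Sequence[BBox],
    iou_thr: float = 0.5,
) -> ApResult:
    """AP at a fixed IoU threshold with all-points interpolation.

    Detections are ranked by descending confidence (ties by input order)
    and matched greedily one-to-one: each detection claims the unclaimed
    reference with the highest IoU, provided IoU >= ``iou_thr``.
    """
    if len(reference_boxes) == 0:
        raise ValueError("empty reference set: AP undefined")
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    claimed = np.zeros(len(reference_boxes), dtype=bool)
    tp_flags = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        best_j, best_iou = -1, iou_thr
        for j, ref in enumerate(reference_boxes):
            if claimed[j]:
                continue
            v = iou(dets[i].box, ref)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            claimed[best_j] = True
            tp_flags[rank] = True

    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / len(reference_boxes)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)

    # all-points interpolation: precision envelope integrated over recall steps
    if len(order) == 0:
        return ApResult(0.0, iou_thr, np.array([]), np.array([]))
    p_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - r_prev) * p_env))
    return ApResult(ap, iou_thr, precision, recall)


def format_confusion_table(
    cm: ConfusionMatrix, target_label: str = "White Pine", other_label: str = "Other"
) -> str:
    """Plain-text 2x2 table with margins, detection outcomes as columns."""
    rows = [
        ("Class", "Detected", "Not Detected", "Total"),
        (target_label, f"{cm.tp} (TP)", f"{cm.fn} (FN)", str(cm.n_target)),
        (other_label, f"{cm.fp} (FP)", f"{cm.tn} (TN)", str(cm.n_other)),
        ("Total", str(cm.tp + cm.fp), str(cm.fn + cm.tn), str(cm.total)),
    ]
    widths = [max(len(r[c]) for r in rows) for c in range(4)]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
    return "\n".join(lines)
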