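"""Detection post-processing: confidence thresholding and NMS.

The study's operating point keeps only detections with confidence >= 0.95
("below the threshold" is excluded, so a box exactly at the threshold is
kept) and removes redundant overlapping boxes by greedy non-maximum
suppression, retaining the highest-confidence box among overlapping ones.
The overlap criterion for NMS is IoU >= 0.5 by default — a convention, as
only the suppression behavior (not its threshold) is fixed by the study
design; it is exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .geometry import BBox, iou

__all__ = ["Detection", "PostConfig", "filter_confidence", "nms", "postprocess"]


@dataclass(frozen=True)
class Detection:
    """A predicted bounding box with a confidence score in [0, 1]."""

    box: BBox
    confidence: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PostConfig:
    conf_threshold: float = 0.95
    nms_iou: float = 0.5
    nms_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise ValueError("conf_threshold must be in [0, 1]")
        if not 0.0 <= self.nms_iou <= 1.0:
            raise ValueError("nms_iou must be in [0, 1]")


def filter_confidence(dets: list[Detection], tau: float) -> list[Detection]:
    """Keep exactly the detections with confidence >= tau, order-stable."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return [d for d in dets if d.confidence >= tau]


def nms(dets: list[Detection], iou_thr: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression in descending confidence order.

    A box is kept iff its IoU with every already-kept box is below
    ``iou_thr``; the output is a subset of the input with pairwise IoU
    below the threshold, ordered by descending confidence. Confidence ties
    break by larger box area, then input order (determinism).
    """
    order = sorted(
        range(len(dets)), key=lambda i: (-dets[i].confidence, -dets[i].box.area, i)
    )
    kept: list[Detection] = []
    for i in order:
        d = dets[i]
        if all(iou(d.box, k.box) < iou_thr for k in kept):
            kept.append(d)
    return kept


def postprocess(dets: list[Detection], cfg: PostConfig = PostConfig()) -> list[Detection]:
    """Default pipeline order: confidence filter, then NMS."""
    out = filter_confidence(dets, cfg.conf_threshold)
    if cfg.nms_enabled:
        out = nms(out, cfg.nms_iou)
    return out
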