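"""Segmentation and detection metrics with a per-region report.

Segmentation is scored pixel-wise (IoU, precision, accuracy from the usual
TP/FP/TN/FN counts).  Detection uses one-to-one greedy box matching: a
predicted box counts as a true positive when it is matched to a ground-truth
box with IoU at or above the threshold.  Recall and precision are reported
per tongue area (root & center merged, tip, margin) and in total, mirroring
how partitioned prickle detectors are usually compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import REGION_NAMES
from .pipeline import BoundingBox

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "DetectionReport",
    "seg_confusion",
    "seg_metrics",
    "bbox_iou",
    "match_detections",
    "detection_report",
]

REPORT_REGIONS = ("root_center", "tip", "margin")


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN counts; TN is zero (undefined) for detection tasks."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def recall(self) -> float | None:
        return None if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float | None:
        return None if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)


def seg_confusion(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts between two binary masks."""
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    return ConfusionCounts(
        tp=int(np.sum(gt & pred)),
        fp=int(np.sum(~gt & pred)),
        tn=int(np.sum(~gt & ~pred)),
        fn=int(np.sum(gt & ~pred)),
    )


def seg_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(IoU, precision, accuracy) of pixel-wise counts.

    A metric with a zero denominator is returned as ``None`` (undefined),
    never silently as 0.
    """
    iou = None if c.tp + c.fp + c.fn == 0 else c.tp / (c.tp + c.fp + c.fn)
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = None if total == 0 else (c.tp + c.tn) / total
    return iou, c.precision, accuracy


def bbox_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    gt: list[BoundingBox], pred: list[BoundingBox], iou_threshold: float = 0.5
) -> ConfusionCounts:
    """One-to-one greedy matching of predictions to ground truth.

    Candidate pairs with IoU >= threshold are consumed in order of
    descending IoU (ties to the smaller gt index, then the smaller pred
    index); each box matches at most once.  TP = matched gt, FN = unmatched
    gt, FP = unmatched predictions; TN is undefined and reported as 0.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")
    counts = _greedy_match(gt, pred, iou_threshold)[0]
    return counts


def _greedy_match(
    gt: list[BoundingBox], pred: list[BoundingBox], iou_threshold: float
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    pairs = [
        (bbox_iou(g, p), gi, pi)
        for gi, g in enumerate(gt)
        for pi, p in enumerate(pred)
        if bbox_iou(g, p) >= iou_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, gi, pi in pairs:
        if gi in matched_gt or pi in matched_pred:
            continue
        matched_gt.add(gi)
        matched_pred.add(pi)
        matches.append((gi, pi))
    counts = ConfusionCounts(
        tp=len(matches), fp=len(pred) - len(matched_pred), fn=len(gt) - len(matched_gt)
    )
    return counts, matches


def _region_key(box: BoundingBox, region_map: np.ndarray) -> str | None:
    cx, cy = box.center
    r, c = int(round(cy)), int(round(cx))
    if not (0 <= r < region_map.shape[0] and 0 <= c < region_map.shape[1]):
        return None
    label = int(region_map[r, c])
    if label == 0:
        return None
    name = REGION_NAMES[label]
    return "root_center" if name in ("root", "center") else name


@dataclass
class DetectionReport:
    """Per-region detection recall/precision in the partitioned layout.

    ``cells`` maps region keys (root_center, tip, margin, total) to
    confusion counts; totals always equal the sum over regions plus any
    boxes whose center fell on background (those are logged and counted in
    the total only).
    """

    cells: dict[str, ConfusionCounts] = field(default_factory=dict)
    iou_threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in (*REPORT_REGIONS, "total"):
            c = self.cells.get(key, ConfusionCounts())
            rows.append(
                {
                    "region": key,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "recall_pct": None if c.recall is None else 100 * c.recall,
                    "precision_pct": None if c.precision is None else 100 * c.precision,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False, na_rep="-")


def detection_report(
    gt_boxes: list[BoundingBox],
    pred_boxes: list[BoundingBox],
    region_map: np.ndarray,
    iou_threshold: float = 0.5,
) -> DetectionReport:
    """Score predictions against ground truth, per tongue area and in total.

    Matching is done once over all boxes; each matched/unmatched box is then
    attributed to the area containing its center (ground truth drives the
    recall cells, predictions the precision cells).  Boxes centered on
    background contribute to the total only, with a logged warning.
    """
    region_map = np.asarray(region_map)
    counts, matches = _greedy_match(gt_boxes, pred_boxes, iou_threshold)
    matched_gt = {gi for gi, _ in matches}
    matched_pred = {pi for _, pi in matches}

    cells = {key: ConfusionCounts() for key in REPORT_REGIONS}
    for gi, g in enumerate(gt_boxes):
        key = _region_key(g, region_map)
        if key is None:
            logger.warning("ground-truth box %s centered on background; counted in total only", g)
        cell = cells.get(key) if key else None
        if cell is not None:
            if gi in matched_gt:
                cell.tp += 1
            else:
                cell.fn += 1
    for pi, p in enumerate(pred_boxes):
        if pi in matched_pred:
            continue
        key = _region_key(p, region_map)
        if key is None:
            logger.warning("predicted box %s centered on background; counted in total only", p)
            continue
        cells[key].fp += 1
    cells["total"] = counts
    return DetectionReport(cells=cells, iou_threshold=iou_threshold)
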