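"""End-to-end annotation pipeline and per-region parameter tuning.

``run_pipeline`` chains the whole workflow on one image: refine the tongue
mask, partition it into root/center/tip/margin, run the multi-threshold
blob detector with each area's parameters, filter the surviving blobs by
redmean color distance to reference prickles, and turn each blob into a
square bounding box.  ``export_labelme``/``import_labelme`` round-trip the
boxes through the Labelme JSON dialect so a human can revise them in the
annotation tool.

``grid_search_params`` tunes one area's detector parameters against
reference boxes: every parameter gets an 11-value grid from 50% to 150% of
its initial value in 10% steps, and a cyclic coordinate search scans one
parameter at a time, accepting the grid value with the best detection F1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .blobs import Blob, BlobParams, detect_blobs, detect_blobs_by_region, to_grayscale
from .color import ReferenceColorSet, filter_blobs_by_color
from .morphology import refine_mask
from .partition import CENTER, MARGIN, REGION_NAMES, ROOT, TIP, PartitionFractions, partition_tongue

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "PipelineResult",
    "GridSearchSpec",
    "blob_to_bbox",
    "annotate_image",
    "run_pipeline",
    "export_labelme",
    "import_labelme",
    "grid_search_params",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in 0-based half-open pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    label: str = "prickle"
    region: str | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center of the box."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


def blob_to_bbox(
    blob: Blob, pad: int = 1, image_size: tuple[int, int] | None = None
) -> BoundingBox:
    """Square box of side ``ceil(diameter + 2*pad)`` centered on the blob.

    ``image_size`` is (height, width); when given, the box is clipped to the
    image bounds.
    """
    side = math.ceil(blob.diameter + 2 * pad)
    cx, cy = blob.center
    x_min = int(math.floor(cx - (blob.diameter + 2 * pad) / 2.0 + 0.5))
    y_min = int(math.floor(cy - (blob.diameter + 2 * pad) / 2.0 + 0.5))
    x_max, y_max = x_min + side, y_min + side
    if image_size is not None:
        h, w = image_size
        x_min, y_min = max(0, x_min), max(0, y_min)
        x_max, y_max = min(w, x_max), min(h, y_max)
    return BoundingBox(x_min, y_min, x_max, y_max, region=blob.region)


@dataclass
class PipelineResult:
    """Intermediate and final products of one annotation run."""

    refined_mask: np.ndarray
    region_map: np.ndarray
    blobs: list[Blob]
    boxes: list[BoundingBox]


def run_pipeline(
    image: np.ndarray,
    mask: np.ndarray,
    config,
    *,
    uniform_params: BlobParams | None = None,
) -> PipelineResult:
    """Refine, partition, detect, color-filter and box one tongue image.

    ``config`` is a :class:`prickle.config.PipelineConfig`.  When
    ``uniform_params`` is given the partition is still computed (boxes keep
    their region attribution) but every area is detected with that single
    parameter set -- the un-partitioned baseline.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    refined = refine_mask(mask)
    region_map = partition_tongue(
        refined, config.fractions, check_refined=False, root_at_top=config.root_at_top
    )
    gray = to_grayscale(image)
    if uniform_params is None:
        params_by_region = config.detector
    else:
        params_by_region = {name: uniform_params for name in ("root", "center", "tip", "margin")}
    blobs = detect_blobs_by_region(gray, region_map, params_by_region)
    blobs = filter_blobs_by_color(blobs, image, config.reference_colors, params_by_region)
    boxes = [blob_to_bbox(b, pad=config.box_pad, image_size=mask.shape) for b in blobs]
    boxes.sort(key=lambda b: (b.y_min, b.x_min))
    return PipelineResult(refined_mask=refined, region_map=region_map, blobs=blobs, boxes=boxes)


def annotate_image(image: np.ndarray, mask: np.ndarray, config) -> list[BoundingBox]:
    """The bounding boxes produced by the full pipeline, sorted by position."""
    return run_pipeline(image, mask, config).boxes


# ---------------------------------------------------------------------------
# Labelme JSON dialect
# ---------------------------------------------------------------------------

_LABELME_VERSION = "5.1.1"


def export_labelme(
    boxes: list[BoundingBox], image_path: str, image_size: tuple[int, int]
) -> dict:
    """Serialize boxes as a Labelme annotation document.

    Each box becomes a rectangle shape with two corner points
    ``[[x_min, y_min], [x_max, y_max]]``; corner values are this package's
    half-open pixel coordinates (the exclusive max corner is written as-is).
    Round-trips losslessly through :func:`import_labelme`.
    """
    h, w = image_size
    shapes = []
    for box in boxes:
        if box.x_max > w or box.y_max > h or box.x_min < 0 or box.y_min < 0:
            raise ValueError(f"box {box} exceeds image bounds {image_size}")
        shapes.append(
            {
                "label": box.label,
                "points": [[float(box.x_min), float(box.y_min)], [float(box.x_max), float(box.y_max)]],
                "group_id": None,
                "description": box.region or "",
                "shape_type": "rectangle",
                "flags": {},
            }
        )
    return {
        "version": _LABELME_VERSION,
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageHeight": int(h),
        "imageWidth": int(w),
    }


def import_labelme(document) -> list[BoundingBox]:
    """Read rectangle shapes from a Labelme document (dict, JSON str or path).

    Corner order is normalized; non-rectangle shapes are skipped with a
    logged warning.
    """
    if isinstance(document, Path):
        document = json.loads(document.read_text())
    elif isinstance(document, str):
        stripped = document.lstrip()
        document = json.loads(
            stripped if stripped.startswith("{") else Path(document).read_text()
        )
    if not isinstance(document, dict) or "shapes" not in document:
        raise ValueError("not a Labelme document: missing 'shapes'")
    boxes: list[BoundingBox] = []
    for shape in document["shapes"]:
        if shape.get("shape_type") != "rectangle":
            logger.warning("skipping non-rectangle shape %r", shape.get("shape_type"))
            continue
        (x0, y0), (x1, y1) = shape["points"]
        region = shape.get("description") or None
        boxes.append(
            BoundingBox(
                x_min=int(round(min(x0, x1))),
                y_min=int(round(min(y0, y1))),
                x_max=int(round(max(x0, x1))),
                y_max=int(round(max(y0, y1))),
                label=shape.get("label", "prickle"),
                region=region,
            )
        )
    return boxes


# ---------------------------------------------------------------------------
# Coordinate-wise grid search for per-region parameters
# ---------------------------------------------------------------------------

_INTEGER_PARAMS = {
    "min_threshold",
    "max_threshold",
    "threshold_step",
    "min_repeatability",
    "min_area",
    "max_area",
}

_DEFAULT_SEARCH_ORDER = (
    "min_threshold",
    "max_threshold",
    "threshold_step",
    "min_repeatability",
    "min_area",
    "max_area",
    "min_circularity",
    "min_convexity",
    "min_inertia_ratio",
    "max_aberration",
)

_REGION_LABELS = {
    "root": (ROOT,),
    "center": (CENTER,),
    "tip": (TIP,),
    "margin": (MARGIN,),
    "root_center": (ROOT, CENTER),
}


@dataclass
class GridSearchSpec:
    """Grid and schedule of the coordinate-wise parameter search.

    Every searched parameter gets the 11-value grid
    ``{0.5, 0.6, ..., 1.5} * initial`` (integer parameters rounded,
    duplicates removed).  The search cycles through ``param_names`` in
    order, scanning one parameter with the others fixed and accepting the
    argmax of the objective (ties resolve to the value closest to the
    initial, then the smaller), until a full cycle changes nothing or
    ``max_cycles`` cycles have run.
    """

    initial: BlobParams
    param_names: tuple[str, ...] = _DEFAULT_SEARCH_ORDER
    step_fraction: float = 0.10
    range_fractions: tuple[float, float] = (0.50, 1.50)
    iou_threshold: float = 0.3
    box_pad: int = 1
    max_cycles: int = 5
    reference_colors: ReferenceColorSet | None = None

    def grid(self, name: str) -> list:
        init = getattr(self.initial, name)
        lo, hi = self.range_fractions
        n = int(round((hi - lo) / self.step_fraction)) + 1
        values = []
        for k in range(n):
            v = (lo + k * self.step_fraction) * init
            if name in _INTEGER_PARAMS:
                v = int(math.floor(v + 0.5))
            values.append(v)
        seen, out = set(), []
        for v in values:
            if v not in seen:
                seen.add(v)
                out.append(v)
        return out


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def _objective(params: BlobParams, prepared, region_labels, spec: GridSearchSpec) -> float:
    from .evaluation import _greedy_match  # local import: evaluation imports this module

    tp = fp = fn = 0
    for gray, image, region_map, gt_boxes in prepared:
        blobs = []
        for blob in detect_blobs(gray, params):
            x, y = blob.center
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < region_map.shape[0] and 0 <= c < region_map.shape[1]):
                continue
            label = int(region_map[r, c])
            if label in region_labels:
                blob.region = REGION_NAMES[label]
                blobs.append(blob)
        if spec.reference_colors is not None:
            uniform = {name: params for name in ("root", "center", "tip", "margin")}
            blobs = filter_blobs_by_color(blobs, image, spec.reference_colors, uniform)
        pred = [blob_to_bbox(b, pad=spec.box_pad, image_size=gray.shape) for b in blobs]
        counts, _ = _greedy_match(gt_boxes, pred, spec.iou_threshold)
        tp, fp, fn = tp + counts.tp, fp + counts.fp, fn + counts.fn
    return _f1(tp, fp, fn)


def grid_search_params(
    scenes: list[tuple[np.ndarray, np.ndarray, list[BoundingBox]]],
    region: str,
    spec: GridSearchSpec,
    fractions: PartitionFractions | None = None,
) -> BlobParams:
    """Coordinate-wise search of one region's detector parameters.

    ``scenes`` holds (image, mask, reference boxes) triples; the objective
    is detection F1 against the reference boxes whose centers fall in
    ``region`` (one of root, center, tip, margin, root_center), at the
    spec's IoU threshold.  The returned parameters never score below the
    initial ones.
    """
    if not scenes:
        raise ValueError("grid search needs at least one scene")
    if region not in _REGION_LABELS:
        raise ValueError(f"unknown region {region!r}")
    labels = set(_REGION_LABELS[region])

    prepared = []
    for image, mask, gt in scenes:
        refined = refine_mask(mask)
        region_map = partition_tongue(refined, fractions, check_refined=False)
        gray = to_grayscale(np.asarray(image))
        gt_region = [b for b in gt if _box_in_labels(b, region_map, labels)]
        prepared.append((gray, np.asarray(image), region_map, gt_region))

    current = spec.initial
    best_score = _objective(current, prepared, labels, spec)
    for _ in range(spec.max_cycles):
        changed = False
        for name in spec.param_names:
            init_value = getattr(spec.initial, name)
            scored = []
            for value in spec.grid(name):
                try:
                    candidate = replace(current, **{name: value})
                except ValueError:
                    continue  # grid value violates a parameter invariant
                score = best_score if value == getattr(current, name) else _objective(
                    candidate, prepared, labels, spec
                )
                scored.append((score, abs(value - init_value), value, candidate))
            if not scored:
                continue
            scored.sort(key=lambda t: (-t[0], t[1], t[2]))
            top_score, _, top_value, top_candidate = scored[0]
            if top_score > best_score and top_value != getattr(current, name):
                current, best_score, changed = top_candidate, top_score, True
        if not changed:
            break
    return current


def _box_in_labels(box: BoundingBox, region_map: np.ndarray, labels: set[int]) -> bool:
    cx, cy = box.center
    r, c = int(round(cy)), int(round(cx))
    if not (0 <= r < region_map.shape[0] and 0 <= c < region_map.shape[1]):
        return False
    return int(region_map[r, c]) in labels
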