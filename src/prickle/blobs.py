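"""Multi-threshold blob detection with shape filters, per tongue region.

Prickles are a few pixels wide and only slightly darker than the coating
around them, so a single binarization threshold is fragile.  The detector
instead sweeps a ladder of gray thresholds, labels the connected components
of every binarization, filters each component by area, circularity,
convexity and inertia ratio, and then groups surviving components across
thresholds by centroid proximity.  A group that reappears at enough
thresholds ("repeatability") becomes one detected blob.  Elongated
structures such as tongue cracks fail the circularity/inertia filters,
which is what lets the tight root/center parameter column suppress them
while the loose tip/margin column keeps faint genuine spots.

Shape-score conventions
-----------------------
* area: pixel count of the component.
* perimeter: the outer boundary is Moore-traced through pixel centers,
  polygonalized with Douglas-Peucker (tolerance 0.8 px) so digitization
  staircases collapse to straight chords, and offset by half a pixel with
  square corner caps (a constant ``+4``).  An ``s x s`` square then scores
  exactly ``4s`` (circularity pi/4) while digitized disks of radius >= 3
  score close to ``2*pi*r``.
* circularity ``4*pi*area/perimeter**2``, clipped to [0, 1].
* convexity: area over the convex-hull area of the pixel centers (the
  contour-based convention of classic blob detectors), clipped to [0, 1];
  defined as 1 for degenerate (single-pixel or collinear) sets.  Digitized
  convex shapes -- squares, disks -- score 1; concave merges score below.
* inertia ratio: smaller over larger eigenvalue of the central second-moment
  matrix of the pixel centers; defined as 1 for a single pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.measure import approximate_polygon

from .partition import REGION_NAMES

__all__ = ["BlobParams", "Blob", "to_grayscale", "shape_scores", "detect_blobs", "detect_blobs_by_region"]

_DP_TOLERANCE = 0.8
_STRUCT8 = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order starting from west, (drow, dcol)
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class BlobParams:
    """Configuration of the multi-threshold detector for one tongue area.

    Defaults are the loose (tip/margin) column of the packaged parameter set;
    gray levels in [0, 255], areas in px^2, score bounds in [0, 1].
    """

    min_threshold: float = 60
    max_threshold: float = 100
    threshold_step: float = 2
    min_repeatability: int = 4
    min_area: float = 2
    max_area: float = 40
    min_circularity: float = 0.4
    min_convexity: float = 0.4
    min_inertia_ratio: float = 0.4
    max_aberration: float = 100.0
    min_dist_between_blobs: float = 10.0
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if not self.min_threshold < self.max_threshold:
            raise ValueError("min_threshold must be < max_threshold")
        if self.threshold_step <= 0:
            raise ValueError("threshold_step must be positive")
        if self.min_repeatability < 1:
            raise ValueError("min_repeatability must be a positive integer")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        for name in ("min_circularity", "min_convexity", "min_inertia_ratio"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_aberration < 0:
            raise ValueError("max_aberration must be non-negative")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")

    def thresholds(self) -> np.ndarray:
        """The threshold ladder: half-open at max_threshold."""
        return np.arange(self.min_threshold, self.max_threshold, self.threshold_step)


@dataclass
class Blob:
    """One detected spot.

    ``center`` is (x, y) in sub-pixel image coordinates; ``repeatability``
    counts at how many thresholds the spot survived all shape filters;
    shape scores come from the member component at the median threshold.
    """

    center: tuple[float, float]
    diameter: float
    area: float
    circularity: float
    convexity: float
    inertia_ratio: float
    repeatability: int
    region: str | None = None
    mean_color: tuple[int, int, int] | None = None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an 8-bit RGB image, rounded half-up."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    luma = 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def _trace_boundary(pixels: set[tuple[int, int]]) -> np.ndarray | None:
    """Moore-neighbour boundary trace (pixel centers); None for single pixels."""
    if len(pixels) == 1:
        return None
    start = min(pixels)
    path = [start]
    cur = start
    backtrack = 0  # index into _MOORE pointing at the neighbour to search first
    first_move = None
    while True:
        for k in range(8):
            idx = (backtrack + k) % 8
            dr, dc = _MOORE[idx]
            nxt = (cur[0] + dr, cur[1] + dc)
            if nxt in pixels:
                break
        else:  # isolated pixel inside a supposedly multi-pixel set
            return None
        if cur == start:
            if first_move is None:
                first_move = idx
            elif idx == first_move:
                # Jacob's stopping criterion: back at the start pixel and
                # about to repeat the very first move.
                break
        path.append(nxt)
        backtrack = ((idx + 4) % 8 + 1) % 8
        cur = nxt
        if len(path) > 8 * len(pixels) + 8:
            break  # safety net; cannot trigger on a connected component
    return np.asarray(path, dtype=float)


def _perimeter(coords: np.ndarray) -> float:
    pixels = set(map(tuple, coords.tolist()))
    path = _trace_boundary(pixels)
    if path is None:
        return 4.0
    poly = approximate_polygon(path, tolerance=_DP_TOLERANCE)
    seg = np.diff(poly, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum()) + 4.0


def shape_scores(coords: np.ndarray) -> tuple[float, float, float, float, float]:
    """(area, perimeter, circularity, convexity, inertia_ratio) of a component.

    ``coords`` is an (N, 2) array of (row, col) pixel coordinates forming one
    8-connected component.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
    if coords.size == 0:
        raise ValueError("empty component")
    area = float(len(coords))
    perimeter = _perimeter(coords)
    circularity = min(1.0, 4.0 * math.pi * area / perimeter**2)

    pts = coords.astype(float)
    try:
        convexity = min(1.0, area / ConvexHull(pts).volume)
    except QhullError:  # single pixel or collinear set: no concavity to score
        convexity = 1.0

    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / area
    ev = np.linalg.eigvalsh(cov)
    inertia = 1.0 if ev[1] < 1e-12 else max(ev[0], 0.0) / ev[1]
    return area, perimeter, circularity, convexity, inertia


@dataclass(frozen=True)
class _Candidate:
    threshold: float
    cy: float
    cx: float
    area: float
    circularity: float
    convexity: float
    inertia_ratio: float


def _threshold_candidates(gray: np.ndarray, t: float, params: BlobParams) -> list[_Candidate]:
    binary = gray < t if params.polarity == "dark" else gray > t
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    wanted = np.flatnonzero((sizes >= params.min_area) & (sizes <= params.max_area))
    wanted = wanted[wanted > 0]
    out: list[_Candidate] = []
    slices = ndimage.find_objects(labels)
    for lbl in wanted:
        sl = slices[lbl - 1]
        sub = labels[sl] == lbl
        rr, cc = np.nonzero(sub)
        coords = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        area, _, circ, conv, inertia = shape_scores(coords)
        if circ < params.min_circularity or conv < params.min_convexity or inertia < params.min_inertia_ratio:
            continue
        cy, cx = coords.mean(axis=0)
        out.append(_Candidate(float(t), float(cy), float(cx), area, circ, conv, inertia))
    return out


def detect_blobs(gray: np.ndarray, params: BlobParams) -> list[Blob]:
    """Run the multi-threshold detector on a gray image.

    For every threshold on the ladder the image is binarized (``dark``:
    pixel < t), components are labeled with 8-connectivity and filtered by
    area and shape scores.  Surviving components are single-link grouped
    across thresholds whenever centroids lie within
    ``min_dist_between_blobs``; groups with at least ``min_repeatability``
    members become blobs.  Each blob's center is the unweighted mean of its
    member centroids and its scores come from the member at the (lower)
    median threshold.  Output sorted by (y, x) of center.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray image must be 2-D")
    candidates: list[_Candidate] = []
    for t in params.thresholds():
        candidates.extend(_threshold_candidates(gray, t, params))
    if not candidates:
        return []
    candidates.sort(key=lambda c: (c.threshold, c.cy, c.cx))

    pts = np.array([(c.cy, c.cx) for c in candidates])
    parent = list(range(len(candidates)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in sorted(cKDTree(pts).query_pairs(params.min_dist_between_blobs)):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[_Candidate]] = {}
    for k, cand in enumerate(candidates):
        groups.setdefault(find(k), []).append(cand)

    blobs: list[Blob] = []
    for members in groups.values():
        if len(members) < params.min_repeatability:
            continue
        cy = float(np.mean([m.cy for m in members]))
        cx = float(np.mean([m.cx for m in members]))
        med = members[(len(members) - 1) // 2]  # members already threshold-sorted
        blobs.append(
            Blob(
                center=(cx, cy),
                diameter=2.0 * math.sqrt(med.area / math.pi),
                area=med.area,
                circularity=med.circularity,
                convexity=med.convexity,
                inertia_ratio=med.inertia_ratio,
                repeatability=len(members),
            )
        )
    blobs.sort(key=lambda b: (b.center[1], b.center[0]))
    return blobs


def _resolve_region_params(name: str, params_by_region: dict[str, BlobParams]) -> BlobParams:
    if name in params_by_region:
        return params_by_region[name]
    if name in ("root", "center") and "root_center" in params_by_region:
        return params_by_region["root_center"]
    raise KeyError(f"no detector parameters configured for region {name!r}")


def detect_blobs_by_region(
    gray: np.ndarray,
    region_map: np.ndarray,
    params_by_region: dict[str, BlobParams],
) -> list[Blob]:
    """Detect blobs with region-specific parameters.

    The detector runs on the full image once per distinct parameter set;
    each blob is assigned the region containing its rounded center and is
    kept only if it was detected under that region's parameters.  Blobs
    centered on background are dropped.
    """
    region_map = np.asarray(region_map)
    if region_map.shape != np.asarray(gray).shape:
        raise ValueError("region map and image dimensions differ")
    present = [int(v) for v in np.unique(region_map) if v != 0]
    region_params = {REGION_NAMES[v]: _resolve_region_params(REGION_NAMES[v], params_by_region) for v in present}

    by_params: dict[BlobParams, list[str]] = {}
    for name, p in region_params.items():
        by_params.setdefault(p, []).append(name)

    blobs: list[Blob] = []
    for params, names in by_params.items():
        for blob in detect_blobs(gray, params):
            x, y = blob.center
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < region_map.shape[0] and 0 <= c < region_map.shape[1]):
                continue
            label = int(region_map[r, c])
            if label == 0:
                continue
            name = REGION_NAMES[label]
            if name in names:
                blob.region = name
                blobs.append(blob)
    blobs.sort(key=lambda b: (b.center[1], b.center[0]))
    return blobs
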