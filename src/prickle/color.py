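"""Redmean chromatic-aberration filtering of detected blobs.

The blob detector works on luma only, so a dark petechia and a red prickle
look alike to it.  Color brings them apart: every detected blob's mean RGB
is compared against a small set of reference prickle colors (exemplars
picked from real prickles, or exported by the synthetic generator) using
the redmean weighted RGB distance, a cheap approximation of perceptual
(LAB-like) color difference:

    rbar = (R1 + R2) / 2
    d    = sqrt((2 + rbar/256)*dR^2 + 4*dG^2 + (2 + (255 - rbar)/256)*dB^2)

A blob is kept when its distance to the closest reference color of its
region stays below that region's ``max_aberration`` bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blobs import Blob, BlobParams

__all__ = ["ReferenceColorSet", "chromatic_aberration", "blob_mean_color", "filter_blobs_by_color"]

RGBColor = tuple[int, int, int]


def _validate_color(c) -> tuple[float, float, float]:
    r, g, b = (float(v) for v in c)
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"RGB channels must lie in [0, 255], got {c}")
    return r, g, b


@dataclass
class ReferenceColorSet:
    """Exemplar prickle colors per tongue region.

    Keys are region names ("root", "center", "tip", "margin") or the merged
    "root_center"; every region the pipeline detects in must resolve to a
    non-empty color list.
    """

    colors_by_region: dict[str, list[RGBColor]] = field(default_factory=dict)

    def for_region(self, name: str) -> list[RGBColor]:
        colors = self.colors_by_region.get(name)
        if colors is None and name in ("root", "center"):
            colors = self.colors_by_region.get("root_center")
        if not colors:
            raise KeyError(f"no reference colors configured for region {name!r}")
        return colors


def chromatic_aberration(c1, c2) -> float:
    """Redmean weighted RGB distance between two 8-bit colors.

    Symmetric, zero iff the colors are identical.
    """
    r1, g1, b1 = _validate_color(c1)
    r2, g2, b2 = _validate_color(c2)
    rbar = (r1 + r2) / 2.0
    dr, dg, db = r1 - r2, g1 - g2, b1 - b2
    return math.sqrt((2 + rbar / 256) * dr * dr + 4 * dg * dg + (2 + (255 - rbar) / 256) * db * db)


def blob_mean_color(image: np.ndarray, blob: Blob) -> RGBColor:
    """Channel-wise mean color over the blob's detection disk.

    Averages the pixels whose centers fall within ``diameter / 2`` of the
    blob center (always at least the center pixel), rounded half-up.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    cx, cy = blob.center
    r_int, c_int = int(round(cy)), int(round(cx))
    if not (0 <= r_int < h and 0 <= c_int < w):
        raise ValueError(f"blob center {blob.center} lies outside the image")
    radius = blob.diameter / 2.0
    lo_r, hi_r = max(0, int(math.floor(cy - radius))), min(h - 1, int(math.ceil(cy + radius)))
    lo_c, hi_c = max(0, int(math.floor(cx - radius))), min(w - 1, int(math.ceil(cx + radius)))
    rr, cc = np.mgrid[lo_r : hi_r + 1, lo_c : hi_c + 1]
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius * radius
    if not inside.any():
        pix = image[r_int, c_int].reshape(1, 3)
    else:
        pix = image[rr[inside], cc[inside]].reshape(-1, 3)
    mean = np.floor(pix.astype(float).mean(axis=0) + 0.5).astype(int)
    return int(mean[0]), int(mean[1]), int(mean[2])


def filter_blobs_by_color(
    blobs: list[Blob],
    image: np.ndarray,
    refs: ReferenceColorSet,
    params_by_region: dict[str, BlobParams],
) -> list[Blob]:
    """Keep blobs whose color matches a reference prickle of their region.

    A blob survives iff the minimum redmean distance between its mean color
    and the region's reference colors is at most the region's
    ``max_aberration``.  Order is preserved; every blob must carry a region.
    """
    from .blobs import _resolve_region_params  # shared region-key resolution

    kept: list[Blob] = []
    for blob in blobs:
        if blob.region is None:
            raise ValueError("blob has no region; run detect_blobs_by_region first")
        params = _resolve_region_params(blob.region, params_by_region)
        color = blob_mean_color(image, blob)
        blob.mean_color = color
        dist = min(chromatic_aberration(color, ref) for ref in refs.for_region(blob.region))
        if dist <= params.max_aberration:
            kept.append(blob)
    return kept
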