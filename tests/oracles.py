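"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written with different algorithms and
libraries than the package code: flood fill instead of two-pass union-find,
direct formula evaluation instead of the packaged distance, per-pixel rule
evaluation instead of vectorized banding, skimage labeling plus brute-force
O(n^2) grouping instead of scipy + KD-tree, and exhaustive recursion instead
of greedy matching.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from prickle.blobs import shape_scores

_OFFS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFS8 = _OFFS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS flood-fill labeling, components numbered in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    offs = _OFFS8 if connectivity == 8 else _OFFS4
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    n = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j] or labels[i, j]:
                continue
            n += 1
            q = deque([(i, j)])
            labels[i, j] = n
            while q:
                r, c = q.popleft()
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = n
                        q.append((rr, cc))
    return labels, n


def redmean_direct(c1, c2) -> float:
    """Direct evaluation of the redmean distance with numpy float arithmetic."""
    a = np.asarray(c1, dtype=np.float64)
    b = np.asarray(c2, dtype=np.float64)
    rbar = (a[0] + b[0]) / 2.0
    d = a - b
    w = np.array([2.0 + rbar / 256.0, 4.0, 2.0 + (255.0 - rbar) / 256.0])
    return float(np.sqrt(np.sum(w * d * d)))


def partition_by_rule(mask: np.ndarray, f_root: float, f_tip: float, f_margin: float) -> np.ndarray:
    """Label every pixel by literal evaluation of the banding rules."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    rows = [r for r in range(h) if mask[r].any()]
    r0, r1 = rows[0], rows[-1]
    length = r1 - r0 + 1
    out = np.zeros((h, w), dtype=np.uint8)
    for r in rows:
        cols = [c for c in range(w) if mask[r, c]]
        left, right = cols[0], cols[-1]
        rel = r - r0
        for c in cols:
            if rel < f_root * length:
                out[r, c] = 1  # root
            elif rel >= (1.0 - f_tip) * length:
                out[r, c] = 3  # tip
            else:
                half_width = (right - left) / 2.0
                if min(c - left, right - c) <= f_margin * half_width:
                    out[r, c] = 4  # margin
                else:
                    out[r, c] = 2  # center
    return out


def exhaustive_detect(gray: np.ndarray, params) -> list[dict]:
    """Materialize every thresholded labeling and group by brute force.

    Shares only ``shape_scores`` with the package (that primitive is pinned by
    closed-form examples elsewhere); thresholding, labeling, filtering and
    grouping are re-derived independently.
    """
    gray = np.asarray(gray)
    candidates = []  # (threshold, cy, cx, area, circ, conv, inertia)
    t = params.min_threshold
    while t < params.max_threshold:
        binary = gray < t if params.polarity == "dark" else gray > t
        lab = sk_label(binary, connectivity=2)
        for prop in regionprops(lab):
            coords = prop.coords
            if not params.min_area <= len(coords) <= params.max_area:
                continue
            area, _, circ, conv, inertia = shape_scores(coords)
            if (
                circ >= params.min_circularity
                and conv >= params.min_convexity
                and inertia >= params.min_inertia_ratio
            ):
                cy, cx = coords.mean(axis=0)
                candidates.append((float(t), float(cy), float(cx), area, circ, conv, inertia))
        t += params.threshold_step
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    n = len(candidates)
    adjacent = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(candidates[i][1] - candidates[j][1], candidates[i][2] - candidates[j][2]) <= params.min_dist_between_blobs:
                adjacent[i].append(j)
                adjacent[j].append(i)
    seen = [False] * n
    blobs = []
    for i in range(n):
        if seen[i]:
            continue
        group, q = [], deque([i])
        seen[i] = True
        while q:
            k = q.popleft()
            group.append(candidates[k])
            for m in adjacent[k]:
                if not seen[m]:
                    seen[m] = True
                    q.append(m)
        if len(group) < params.min_repeatability:
            continue
        group.sort(key=lambda c: (c[0], c[1], c[2]))
        med = group[(len(group) - 1) // 2]
        blobs.append(
            {
                "center": (
                    float(np.mean([g[2] for g in group])),  # x
                    float(np.mean([g[1] for g in group])),  # y
                ),
                "area": med[3],
                "circularity": med[4],
                "convexity": med[5],
                "inertia_ratio": med[6],
                "repeatability": len(group),
            }
        )
    blobs.sort(key=lambda b: (b["center"][1], b["center"][0]))
    return blobs


def best_matching_size(gt, pred, iou_of, threshold: float) -> int:
    """Size of a maximum one-to-one matching, by exhaustive recursion."""
    pairs = [
        [pi for pi, p in enumerate(pred) if iou_of(g, p) >= threshold] for g in gt
    ]

    def recurse(gi: int, used: frozenset) -> int:
        if gi == len(pairs):
            return 0
        best = recurse(gi + 1, used)  # leave this gt unmatched
        for pi in pairs[gi]:
            if pi not in used:
                best = max(best, 1 + recurse(gi + 1, used | {pi}))
        return best

    return recurse(0, frozenset())
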