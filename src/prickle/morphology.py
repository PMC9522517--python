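"""Connected-component mask refinement.

A segmentation network classifies pixels independently, so its tongue masks
come back with pinhole gaps inside the tongue and speckle islands outside it.
This module repairs such masks with plain connected-component reasoning:
keep the largest foreground component, then flood everything that is not part
of the largest background component.  The labeling itself is the classic
two-pass algorithm (raster scan collecting provisional labels and union-find
equivalences, second raster scan resolving them), compiled with numba so that
full-resolution masks refine in milliseconds.

Conventions
-----------
* Foreground components use 8-connectivity, background 4-connectivity --
  the standard dual pairing that avoids a closed curve and its interior
  being simultaneously "connected" to the outside.
* The image border is treated as adjacent to an implicit exterior, so all
  background touching the border belongs to one component.
* Final labels are consecutive ``1..n`` in first-encounter raster order,
  which makes "largest component, ties to the earliest raster pixel" a
  simple ``argmax`` over label sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["LabelGrid", "NoForegroundError", "two_pass_label", "refine_mask"]


class NoForegroundError(ValueError):
    """Raised when a mask that must contain a tongue is entirely background."""


@dataclass(frozen=True)
class LabelGrid:
    """Result of a connected-component labeling run.

    Attributes
    ----------
    labels:
        2-D int32 array; 0 marks pixels outside every component, components
        are numbered ``1..n_components`` in first-encounter raster order.
    n_components:
        Number of distinct components.
    """

    labels: np.ndarray
    n_components: int

    def sizes(self) -> np.ndarray:
        """Pixel count per component, index 0 unused."""
        return np.bincount(self.labels.ravel(), minlength=self.n_components + 1)


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


@njit(cache=False)
def _find(parent, x):  # pragma: no cover - exercised through two_pass_label
    root = x
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


@njit(cache=False)
def _union(parent, a, b):  # pragma: no cover
    ra = _find(parent, a)
    rb = _find(parent, b)
    if ra != rb:
        # keep the smaller root so provisional ordering stays raster-stable
        if ra < rb:
            parent[rb] = ra
        else:
            parent[ra] = rb


@njit(cache=False)
def _two_pass_core(mask, eight):  # pragma: no cover
    h, w = mask.shape
    labels = np.zeros((h, w), np.int32)
    # worst case for 4/8-connectivity: checkerboard, (h*w+1)//2 components
    parent = np.zeros(h * w // 2 + 2, np.int32)
    nxt = 1
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            best = 0
            # previously-scanned neighbours: W, N (+ NW, NE for 8-conn)
            if j > 0 and mask[i, j - 1]:
                best = labels[i, j - 1]
            if i > 0:
                if mask[i - 1, j]:
                    l = labels[i - 1, j]
                    if best == 0 or l < best:
                        best = l
                if eight:
                    if j > 0 and mask[i - 1, j - 1]:
                        l = labels[i - 1, j - 1]
                        if best == 0 or l < best:
                            best = l
                    if j + 1 < w and mask[i - 1, j + 1]:
                        l = labels[i - 1, j + 1]
                        if best == 0 or l < best:
                            best = l
            if best == 0:
                parent[nxt] = nxt
                labels[i, j] = nxt
                nxt += 1
            else:
                labels[i, j] = best
                if j > 0 and mask[i, j - 1]:
                    _union(parent, best, labels[i, j - 1])
                if i > 0:
                    if mask[i - 1, j]:
                        _union(parent, best, labels[i - 1, j])
                    if eight:
                        if j > 0 and mask[i - 1, j - 1]:
                            _union(parent, best, labels[i - 1, j - 1])
                        if j + 1 < w and mask[i - 1, j + 1]:
                            _union(parent, best, labels[i - 1, j + 1])
    # second pass: resolve equivalences, renumber in first-encounter order
    final = np.zeros(nxt, np.int32)
    count = 0
    for i in range(h):
        for j in range(w):
            l = labels[i, j]
            if l == 0:
                continue
            root = _find(parent, l)
            if final[root] == 0:
                count += 1
                final[root] = count
            labels[i, j] = final[root]
    return labels, count


def two_pass_label(mask: np.ndarray, connectivity: int = 8) -> LabelGrid:
    """Label connected foreground components with a two-pass raster scan.

    Parameters
    ----------
    mask:
        2-D boolean (or boolean-like) array; ``True`` is foreground.
    connectivity:
        4 or 8; neighbourhood under which pixels are considered connected.

    Returns
    -------
    LabelGrid
        Components numbered consecutively in first-encounter raster order.
    """
    mask = _as_bool_mask(mask)
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = _two_pass_core(mask.astype(np.uint8), connectivity == 8)
    return LabelGrid(labels=labels, n_components=int(n))


def _largest_label(lg: LabelGrid, sizes: np.ndarray) -> int:
    # argmax returns the first maximum; labels are in first-encounter raster
    # order, so ties resolve to the component whose first pixel comes first.
    return int(np.argmax(sizes[1:]) + 1)


def refine_mask(mask: np.ndarray) -> np.ndarray:
    """Reduce a noisy tongue mask to one solid, hole-free region.

    Keeps the largest 8-connected foreground component, then re-labels the
    background with 4-connectivity (border-adjacent background counts as one
    exterior component) and keeps only the largest background component:
    every other background component is an interior hole and is filled.

    Idempotent; the result has exactly one foreground component and at most
    one background component.

    Raises
    ------
    NoForegroundError
        If the mask contains no foreground pixel.
    """
    mask = _as_bool_mask(mask)
    fg = two_pass_label(mask, 8)
    if fg.n_components == 0:
        raise NoForegroundError("mask contains no foreground pixels; no tongue found")
    keep = _largest_label(fg, fg.sizes())
    solid = fg.labels == keep

    # background labeling on a padded grid so the exterior is one component
    padded_bg = np.pad(~solid, 1, constant_values=True)
    bg = two_pass_label(padded_bg, 4)
    inner = bg.labels[1:-1, 1:-1]
    # component sizes counted over real (unpadded) pixels only
    sizes = np.bincount(inner.ravel(), minlength=bg.n_components + 1)
    sizes[0] = 0
    if sizes.sum() == 0:
        return solid  # mask fills the whole frame: nothing to fill
    keep_bg = int(np.argmax(sizes))
    return solid | ((inner != keep_bg) & (inner > 0))
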