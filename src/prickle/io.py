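"""PNG input/output for images, binary masks and region maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask", "read_region_map", "write_region_map"]


def read_image(path: str | Path) -> np.ndarray:
    """8-bit RGB image as an (H, W, 3) array."""
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask from a single-channel PNG: any nonzero pixel is foreground."""
    return np.asarray(Image.open(path).convert("L")) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 grayscale PNG."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_region_map(path: str | Path) -> np.ndarray:
    """Region label grid (0 background, 1 root, 2 center, 3 tip, 4 margin)."""
    img = Image.open(path)
    # palettized PNGs store the label indices directly; don't flatten to luma
    arr = np.asarray(img) if img.mode == "P" else np.asarray(img.convert("L"))
    if arr.max() > 4:
        raise ValueError(f"{path} does not look like a region map (labels up to {arr.max()})")
    return arr.astype(np.uint8)


def write_region_map(path: str | Path, region_map: np.ndarray) -> None:
    arr = np.asarray(region_map, dtype=np.uint8)
    img = Image.fromarray(arr, mode="P")
    # visual palette: background, root, center, tip, margin
    img.putpalette([0, 0, 0, 200, 60, 60, 240, 180, 80, 80, 170, 240, 110, 200, 110] + [0] * (256 * 3 - 15))
    img.save(path)
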