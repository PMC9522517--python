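"""Seeded generator of device-like tongue scenes with full ground truth.

The scenes emulate images from a closed tongue-acquisition box: a pinkish
tongue blob on a dark background, a whitish coating that thickens toward
the root and center, small reddish prickles (a few pixels each, biased
toward tip and margin), plus the two distractor classes that plague spot
detectors on real tongues -- dark crack fragments in the root/center band
and larger dark-purple petechiae.  Each scene also carries a clean tongue
mask, a degraded copy of it (interior holes plus exterior speckles, the
kind of damage a per-pixel segmenter produces) and bounding boxes for every
planted structure, so every pipeline stage can be scored without any
external data.

Geometry and photometry are chosen so the packaged detector parameter set
is exercised meaningfully: prickle cores sit ~75 luma levels below the
tongue body (threshold ladder 60-100 catches them at 12-16 levels), crack
fragments are slightly elongated dark-red blobs of ~28-36 px that pass the
loose tip/margin filters but fail the tight root/center area and inertia
bounds, and petechiae are large enough (>=55 px) to fail every area bound.
Root/center prickles are drawn a little larger than tip/margin ones -- the
coating veils their rims, and their thresholded cores must stay inside the
tight 4-25 px area band while remaining round enough to pass the 0.8
circularity bound at integer-pixel resolution.

Randomness is split into one independent stream per scene element (tongue,
coating, prickles, cracks, petechiae, noise, mask degradation), so changing
the crack count does not reshuffle prickle placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .partition import CENTER, MARGIN, ROOT, TIP, PartitionFractions, partition_tongue
from .pipeline import BoundingBox

__all__ = [
    "TongueSpec",
    "CoatingSpec",
    "PrickleSpec",
    "CrackSpec",
    "PetechiaSpec",
    "MaskDegradationSpec",
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "degrade_mask",
    "generate_suite",
    "fast_spec",
]

_CATEGORIES = ("root_center", "tip", "margin")
_CATEGORY_LABELS = {"root_center": (ROOT, CENTER), "tip": (TIP,), "margin": (MARGIN,)}


@dataclass(frozen=True)
class TongueSpec:
    """Superellipse tongue silhouette and base color.

    Half-axes are fractions of the image size; the vertical profile uses a
    flatter exponent above the widest row (broad root) and a rounder one
    below it (tip rounding).
    """

    center_row_frac: float = 0.50
    center_col_frac: float = 0.50
    half_width_frac: float = 0.30
    half_length_up_frac: float = 0.36
    half_length_down_frac: float = 0.40
    lateral_exponent: float = 2.4
    root_exponent: float = 4.0
    tip_exponent: float = 2.2
    base_rgb: tuple[int, int, int] = (192, 118, 122)
    noise_sd: float = 5.0


@dataclass(frozen=True)
class CoatingSpec:
    """Whitish coating overlay, thickest toward root and center."""

    rgb: tuple[int, int, int] = (216, 208, 196)
    max_opacity: float = 0.55
    length_falloff: float = 0.75  # coating vanishes past this fraction of the length
    edge_exponent: float = 0.35  # radial fade toward the tongue contour


@dataclass(frozen=True)
class PrickleSpec:
    """Planted prickles: reddish plateau disks with a soft 0.6 px rim."""

    count: int = 15
    radius_root_center: tuple[float, float] = (2.9, 3.15)
    radius_tip_margin: tuple[float, float] = (2.0, 3.2)
    rgb: tuple[int, int, int] = (115, 30, 42)
    rgb_jitter: tuple[float, float, float] = (6.0, 5.0, 5.0)
    region_weights: tuple[float, float, float] = (0.15, 0.50, 0.35)  # root_center, tip, margin
    min_separation: float = 12.0
    rim: float = 0.6


@dataclass(frozen=True)
class CrackSpec:
    """Crack-like distractors: chains of short dark-red elliptical dashes.

    Real tongue cracks read as beaded dark lines where the coating is
    interrupted; each bead is its own connected component once thresholded.
    Dash centers are spaced farther apart than the detector's blob-merge
    distance so every dash is an independent false-positive candidate.
    """

    count: int = 4
    dashes_per_crack: tuple[int, int] = (3, 5)
    dash_half_axes: tuple[float, float] = (3.0, 4.2)  # across, along the crack
    dash_spacing: float = 11.5
    rgb: tuple[int, int, int] = (120, 48, 55)
    rim: float = 0.25  # as a fraction of the normalized ellipse radius


@dataclass(frozen=True)
class PetechiaSpec:
    """Dark-purple blood spots, larger and darker than prickles."""

    count: int = 3
    radius: tuple[float, float] = (4.3, 5.8)
    rgb: tuple[int, int, int] = (75, 32, 66)
    rim: float = 0.8


@dataclass(frozen=True)
class MaskDegradationSpec:
    """Interior holes and exterior speckles punched into the clean mask."""

    holes: int = 3
    hole_radius: tuple[float, float] = (3.0, 8.0)
    speckles: int = 5
    speckle_radius: tuple[float, float] = (2.0, 5.0)


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic tongue scene."""

    seed: int = 0
    image_size: tuple[int, int] = (768, 576)  # (H, W): portrait device frame
    background_rgb: tuple[int, int, int] = (18, 16, 20)
    tongue: TongueSpec = field(default_factory=TongueSpec)
    coating: CoatingSpec = field(default_factory=CoatingSpec)
    prickles: PrickleSpec = field(default_factory=PrickleSpec)
    cracks: CrackSpec = field(default_factory=CrackSpec)
    petechiae: PetechiaSpec = field(default_factory=PetechiaSpec)
    mask_degradation: MaskDegradationSpec = field(default_factory=MaskDegradationSpec)
    partition_fractions: PartitionFractions = field(default_factory=PartitionFractions)

    def __post_init__(self) -> None:
        h, w = self.image_size
        t = self.tongue
        if t.center_row_frac - t.half_length_up_frac < 0 or t.center_row_frac + t.half_length_down_frac > 1:
            raise ValueError("tongue taller than the image")
        if t.center_col_frac - t.half_width_frac < 0 or t.center_col_frac + t.half_width_frac > 1:
            raise ValueError("tongue wider than the image")
        for n in (self.prickles.count, self.cracks.count, self.petechiae.count):
            if n < 0:
                raise ValueError("element counts must be non-negative")


@dataclass
class SceneTruth:
    """A rendered scene plus everything needed to score the pipeline on it."""

    image: np.ndarray
    clean_mask: np.ndarray
    degraded_mask: np.ndarray
    region_map: np.ndarray
    prickle_boxes: list[BoundingBox]
    crack_boxes: list[BoundingBox]
    petechia_boxes: list[BoundingBox]
    prickle_colors: list[tuple[int, int, int]]
    spec: SceneSpec

    def reference_colors(self) -> dict[str, list[tuple[int, int, int]]]:
        """Ground-truth prickle palette per area, measured from the image.

        Emulates "picking prickles by hand": for every planted prickle, the
        mean rendered color over its core disk.  The nominal prickle color
        is always included so areas without a planted prickle still have an
        exemplar.
        """
        nominal = tuple(int(v) for v in self.spec.prickles.rgb)
        out: dict[str, list[tuple[int, int, int]]] = {cat: [nominal] for cat in _CATEGORIES}
        h, w = self.image.shape[:2]
        for box in self.prickle_boxes:
            cx, cy = box.center
            radius = max(1.0, 0.4 * (box.x_max - box.x_min))
            rr, cc = np.mgrid[
                max(0, int(cy - radius)) : min(h, int(cy + radius) + 1),
                max(0, int(cx - radius)) : min(w, int(cx + radius) + 1),
            ]
            inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius * radius
            pix = self.image[rr[inside], cc[inside]].reshape(-1, 3)
            mean = tuple(int(v) for v in np.floor(pix.mean(axis=0) + 0.5))
            key = "root_center" if box.region in ("root", "center") else box.region
            if key in out:
                out[key].append(mean)
        return out


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("tongue", "coating", "prickles", "cracks", "petechiae", "noise", "degradation")
    return {name: np.random.default_rng([seed, i]) for i, name in enumerate(names)}


def _tongue_field(spec: SceneSpec) -> np.ndarray:
    """Normalized superellipse coordinate: <= 1 inside the tongue."""
    h, w = spec.image_size
    t = spec.tongue
    cr, cc = t.center_row_frac * h, t.center_col_frac * w
    a = t.half_width_frac * w
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    b = np.where(rows < cr, t.half_length_up_frac * h, t.half_length_down_frac * h)
    q = np.where(rows < cr, t.root_exponent, t.tip_exponent)
    u = np.abs(rows - cr) / b
    v = np.abs(cols - cc) / a
    return v**t.lateral_exponent + u**q


def _paint_disk(img: np.ndarray, cy: float, cx: float, radius: float, rim: float, color) -> None:
    h, w = img.shape[:2]
    r0 = max(0, int(math.floor(cy - radius - rim - 1)))
    r1 = min(h, int(math.ceil(cy + radius + rim + 2)))
    c0 = max(0, int(math.floor(cx - radius - rim - 1)))
    c1 = min(w, int(math.ceil(cx + radius + rim + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rho = np.hypot(rr - cy, cc - cx)
    wgt = np.clip((radius + rim - rho) / (2 * rim), 0.0, 1.0)
    img[r0:r1, c0:c1] = (1 - wgt[..., None]) * img[r0:r1, c0:c1] + wgt[..., None] * np.asarray(color, float)


def _paint_ellipse(img, cy, cx, half_across, half_along, angle, rim_frac, color) -> None:
    h, w = img.shape[:2]
    ext = max(half_across, half_along) * (1 + rim_frac) + 2
    r0, r1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 1)
    c0, c1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    along = dy * math.cos(angle) + dx * math.sin(angle)
    across = -dy * math.sin(angle) + dx * math.cos(angle)
    d = np.hypot(along / half_along, across / half_across)
    wgt = np.clip(((1 + rim_frac) - d) / (2 * rim_frac), 0.0, 1.0)
    img[r0:r1, c0:c1] = (1 - wgt[..., None]) * img[r0:r1, c0:c1] + wgt[..., None] * np.asarray(color, float)


def _sample_positions(
    rng: np.random.Generator,
    allowed: np.ndarray,
    edt: np.ndarray,
    n: int,
    clearance: float,
    min_separation: float,
    taken: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Sample n sub-pixel positions on `allowed` pixels, away from the mask
    boundary (`edt >= clearance`) and from previously taken positions."""
    positions: list[tuple[float, float]] = []
    for relax in (1.0, 0.6, 0.3):
        ok = allowed & (edt >= max(2.0, clearance * relax))
        idx = np.flatnonzero(ok.ravel())
        if idx.size == 0:
            continue
        w = ok.shape[1]
        tries = 0
        while len(positions) < n and tries < 400 * n:
            tries += 1
            flat = int(rng.choice(idx))
            cy = flat // w + rng.uniform(-0.5, 0.5)
            cx = flat % w + rng.uniform(-0.5, 0.5)
            if all(
                math.hypot(cy - ty, cx - tx) >= min_separation for ty, tx in (*taken, *positions)
            ):
                positions.append((cy, cx))
        if len(positions) >= n:
            break
    return positions


def _disk_box(cy: float, cx: float, radius: float, shape, region: str | None, label: str) -> BoundingBox:
    h, w = shape
    return BoundingBox(
        x_min=max(0, int(math.floor(cx - radius - 0.5))),
        y_min=max(0, int(math.floor(cy - radius - 0.5))),
        x_max=min(w, int(math.ceil(cx + radius + 0.5))),
        y_max=min(h, int(math.ceil(cy + radius + 0.5))),
        label=label,
        region=region,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render one scene deterministically from its spec."""
    h, w = spec.image_size
    rngs = _streams(spec.seed)

    d = _tongue_field(spec)
    clean_mask = d <= 1.0
    region_map = partition_tongue(clean_mask, spec.partition_fractions, check_refined=False)

    img = np.empty((h, w, 3), float)
    img[:] = spec.background_rgb
    img[clean_mask] = spec.tongue.base_rgb

    # coating: opacity ramps down the tongue and fades toward the contour
    rows_with = np.flatnonzero(clean_mask.any(axis=1))
    r_top, r_bot = rows_with[0], rows_with[-1]
    rel_len = np.clip((np.arange(h) - r_top) / max(1, r_bot - r_top), 0, 1)[:, None]
    c = spec.coating
    alpha = (
        c.max_opacity
        * np.clip(1 - rel_len / c.length_falloff, 0, 1) ** 1.1
        * np.clip(1 - d, 0, 1) ** c.edge_exponent
    )
    alpha = np.where(clean_mask, alpha, 0.0)[..., None]
    img = (1 - alpha) * img + alpha * np.asarray(c.rgb, float)

    edt = ndimage.distance_transform_edt(clean_mask)

    # prickles are sampled first, from their own stream and an initially
    # empty exclusion list, so distractor counts never reshuffle them;
    # they are painted last so nothing overdraws a planted spot.
    pk = spec.prickles
    rng = rngs["prickles"]
    counts = rng.multinomial(pk.count, np.asarray(pk.region_weights) / sum(pk.region_weights))
    planted: list[tuple[float, float, float, tuple[int, int, int]]] = []
    taken: list[tuple[float, float]] = []
    for cat, n_cat in zip(_CATEGORIES, counts):
        labels = _CATEGORY_LABELS[cat]
        allowed = np.isin(region_map, labels)
        lo, hi = pk.radius_root_center if cat == "root_center" else pk.radius_tip_margin
        placed = _sample_positions(rng, allowed, edt, int(n_cat), hi + 4, pk.min_separation, taken)
        for cy, cx in placed:
            radius = rng.uniform(lo, hi)
            color = tuple(
                int(np.clip(base + rng.normal(0, sd), 0, 255))
                for base, sd in zip(pk.rgb, pk.rgb_jitter)
            )
            taken.append((cy, cx))
            planted.append((cy, cx, radius, color))

    # crack fragments: beaded dark lines in the root/center band
    ck = spec.cracks
    crack_boxes: list[BoundingBox] = []
    rng = rngs["cracks"]
    rc_mask = (region_map == ROOT) | (region_map == CENTER)
    for _ in range(ck.count):
        starts = _sample_positions(rng, rc_mask, edt, 1, ck.dash_half_axes[1] + 5, 18.0, taken)
        if not starts:
            continue
        sy, sx = starts[0]
        angle = rng.uniform(-0.6, 0.6)  # around the vertical tongue axis
        n_dash = int(rng.integers(ck.dashes_per_crack[0], ck.dashes_per_crack[1] + 1))
        for k in range(n_dash):
            cy = sy + k * ck.dash_spacing * math.cos(angle)
            cx = sx + k * ck.dash_spacing * math.sin(angle)
            r_i, c_i = int(round(cy)), int(round(cx))
            if not (0 <= r_i < h and 0 <= c_i < w):
                break
            if region_map[r_i, c_i] not in (ROOT, CENTER) or edt[r_i, c_i] < ck.dash_half_axes[1] + 3:
                break
            if any(math.hypot(cy - py, cx - px) < 10.0 for py, px, _, _ in planted):
                break  # never overdraw a planted prickle
            _paint_ellipse(img, cy, cx, ck.dash_half_axes[0], ck.dash_half_axes[1], angle, ck.rim, ck.rgb)
            taken.append((cy, cx))
            crack_boxes.append(
                _disk_box(cy, cx, ck.dash_half_axes[1], (h, w), None, "crack")
            )

    # petechiae: large dark-purple disks in root/center
    pt = spec.petechiae
    petechia_boxes: list[BoundingBox] = []
    rng = rngs["petechiae"]
    for cy, cx in _sample_positions(
        rng, rc_mask, edt, pt.count, pt.radius[1] + 4, 16.0, taken
    ):
        radius = rng.uniform(*pt.radius)
        _paint_disk(img, cy, cx, radius, pt.rim, pt.rgb)
        taken.append((cy, cx))
        petechia_boxes.append(_disk_box(cy, cx, radius, (h, w), None, "petechia"))

    # prickles: plateau disks with region-dependent size, tip/margin biased
    prickle_boxes: list[BoundingBox] = []
    prickle_colors: list[tuple[int, int, int]] = []
    for cy, cx, radius, color in planted:
        _paint_disk(img, cy, cx, radius, pk.rim, color)
        region = {ROOT: "root", CENTER: "center", TIP: "tip", MARGIN: "margin"}[
            int(region_map[int(round(cy)), int(round(cx))])
        ]
        prickle_boxes.append(_disk_box(cy, cx, radius, (h, w), region, "prickle"))
        prickle_colors.append(color)

    noise = rngs["noise"].normal(0.0, spec.tongue.noise_sd, size=img.shape)
    image = np.clip(np.floor(img + noise + 0.5), 0, 255).astype(np.uint8)

    degraded = degrade_mask(clean_mask, spec.mask_degradation, rngs["degradation"])

    return SceneTruth(
        image=image,
        clean_mask=clean_mask,
        degraded_mask=degraded,
        region_map=region_map,
        prickle_boxes=sorted(prickle_boxes, key=lambda b: (b.y_min, b.x_min)),
        crack_boxes=sorted(crack_boxes, key=lambda b: (b.y_min, b.x_min)),
        petechia_boxes=sorted(petechia_boxes, key=lambda b: (b.y_min, b.x_min)),
        prickle_colors=prickle_colors,
        spec=spec,
    )


def degrade_mask(
    mask: np.ndarray,
    spec: MaskDegradationSpec,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Punch interior holes and add exterior speckles to a clean mask.

    Holes stay strictly inside the foreground and speckles strictly outside
    it (two-pixel clearance each), so mask refinement recovers the clean
    mask exactly.  Raises if a requested hole cannot fit inside the mask.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    area = int(mask.sum())
    if area == 0:
        raise ValueError("cannot degrade an empty mask")

    edt_in = ndimage.distance_transform_edt(mask)
    for _ in range(spec.holes):
        radius = rng.uniform(*spec.hole_radius)
        if math.pi * radius**2 >= area / 2:
            raise ValueError("hole larger than half the mask area")
        ok = np.flatnonzero((edt_in >= radius + 2).ravel())
        if ok.size == 0:
            raise ValueError("no room for an interior hole of this size")
        flat = int(rng.choice(ok))
        cy, cx = divmod(flat, mask.shape[1])
        rr, cc = np.mgrid[
            max(0, int(cy - radius - 1)) : min(mask.shape[0], int(cy + radius + 2)),
            max(0, int(cx - radius - 1)) : min(mask.shape[1], int(cx + radius + 2)),
        ]
        out[rr[(rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2], cc[(rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2]] = False

    edt_out = ndimage.distance_transform_edt(~mask)
    for _ in range(spec.speckles):
        radius = rng.uniform(*spec.speckle_radius)
        if math.pi * radius**2 >= area:
            raise ValueError("speckle would rival the tongue in size")
        ok = np.flatnonzero((edt_out >= radius + 2).ravel())
        if ok.size == 0:
            continue
        flat = int(rng.choice(ok))
        cy, cx = divmod(flat, mask.shape[1])
        rr, cc = np.mgrid[
            max(0, int(cy - radius - 1)) : min(mask.shape[0], int(cy + radius + 2)),
            max(0, int(cx - radius - 1)) : min(mask.shape[1], int(cx + radius + 2)),
        ]
        sel = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        out[rr[sel], cc[sel]] = True
    return out


def fast_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A scaled-down scene (256 x 192) for quick tests.

    Absolute feature sizes (prickle radii, dash axes) are kept so detector
    parameters stay meaningful; only the canvas and counts shrink.
    """
    defaults = dict(
        seed=seed,
        image_size=(256, 192),
        prickles=PrickleSpec(count=8, min_separation=11.0),
        cracks=CrackSpec(count=2),
        petechiae=PetechiaSpec(count=1),
        mask_degradation=MaskDegradationSpec(holes=2, hole_radius=(2.0, 5.0), speckles=3, speckle_radius=(1.5, 3.0)),
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


def generate_suite(
    n_scenes: int, base_spec: SceneSpec | None = None, seed: int | None = None, out_dir=None
) -> list[SceneTruth]:
    """Generate ``n_scenes`` scenes; scene ``i`` uses seed ``seed + i``.

    With ``out_dir`` set, writes the CLI directory layout: ``images/``,
    ``masks/``, ``masks_degraded/``, ``regions/``, ``truth/*.json``
    (Labelme) and ``truth/colors.yaml`` (aggregated reference palette).
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    base_spec = base_spec or SceneSpec()
    seed = base_spec.seed if seed is None else seed
    scenes = [generate_scene(replace(base_spec, seed=seed + i)) for i in range(n_scenes)]
    if out_dir is not None:
        _write_suite(scenes, out_dir)
    return scenes


def _write_suite(scenes: list[SceneTruth], out_dir) -> None:
    import json
    from pathlib import Path

    import yaml

    from .io import write_image, write_mask, write_region_map
    from .pipeline import export_labelme

    out = Path(out_dir)
    for sub in ("images", "masks", "masks_degraded", "regions", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    palette: dict[str, list] = {cat: [] for cat in _CATEGORIES}
    for i, scene in enumerate(scenes):
        stem = f"scene_{i:04d}"
        write_image(out / "images" / f"{stem}.png", scene.image)
        write_mask(out / "masks" / f"{stem}.png", scene.clean_mask)
        write_mask(out / "masks_degraded" / f"{stem}.png", scene.degraded_mask)
        write_region_map(out / "regions" / f"{stem}.png", scene.region_map)
        doc = export_labelme(scene.prickle_boxes, f"../images/{stem}.png", scene.image.shape[:2])
        (out / "truth" / f"{stem}.json").write_text(json.dumps(doc, indent=2))
        for cat, colors in scene.reference_colors().items():
            palette[cat].extend(list(map(int, c)) for c in colors)
    with open(out / "truth" / "colors.yaml", "w") as fh:
        yaml.safe_dump({"reference_colors": palette}, fh, sort_keys=False)
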