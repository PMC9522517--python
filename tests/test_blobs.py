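"""Multi-threshold blob detector: shape scores, grouping, region routing."""

from __future__ import annotations

import math

import numpy as np
import pytest

from oracles import exhaustive_detect
from prickle import BlobParams, detect_blobs, detect_blobs_by_region, shape_scores, to_grayscale
from prickle.partition import CENTER, MARGIN, TIP

TIGHT = BlobParams(
    min_repeatability=8,
    min_area=4,
    max_area=25,
    min_circularity=0.8,
    min_convexity=0.8,
    min_inertia_ratio=0.5,
    max_aberration=85,
)  # the packaged root/center column
LOOSE = BlobParams()  # defaults are the packaged tip/margin column


def paint_disk(img, cy, cx, r, value):
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r * r] = value


class TestGrayscale:
    def test_white_black_and_red(self):
        img = np.zeros((1, 3, 3), dtype=np.uint8)
        img[0, 0] = (255, 255, 255)
        img[0, 1] = (0, 0, 0)
        img[0, 2] = (255, 0, 0)
        assert list(to_grayscale(img)[0]) == [255, 0, 76]

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestShapeScores:
    def test_single_pixel(self):
        area, perimeter, circ, conv, inertia = shape_scores(np.array([[5, 7]]))
        assert area == 1.0
        assert perimeter == 4.0
        assert inertia == 1.0
        assert conv == 1.0

    @pytest.mark.parametrize("s", [3, 6, 10])
    def test_square_closed_form(self, s):
        rr, cc = np.mgrid[0:s, 0:s]
        coords = np.column_stack([rr.ravel() + 4, cc.ravel() + 9])
        area, perimeter, circ, conv, inertia = shape_scores(coords)
        assert area == s * s
        assert perimeter == pytest.approx(4 * s, abs=1e-9)
        assert circ == pytest.approx(math.pi / 4, abs=1e-9)
        assert conv == pytest.approx(1.0, abs=1e-9)
        assert inertia == pytest.approx(1.0, abs=1e-9)

    def test_digitized_disk_radius6(self):
        rr, cc = np.mgrid[0:31, 0:31]
        coords = np.column_stack(np.nonzero((rr - 15) ** 2 + (cc - 15) ** 2 <= 36))
        area, perimeter, circ, conv, inertia = shape_scores(coords)
        assert area == 113
        assert circ >= 0.85
        assert conv >= 0.95
        assert inertia >= 0.9

    def test_elongated_rectangle_scores_low(self):
        rr, cc = np.mgrid[0:2, 0:12]
        area, _, circ, conv, inertia = shape_scores(np.column_stack([rr.ravel(), cc.ravel()]))
        assert circ < 0.6
        assert inertia < 0.1
        assert conv == pytest.approx(1.0, abs=1e-9)

    def test_concave_cross_has_low_convexity(self):
        block = np.zeros((15, 15), dtype=bool)
        block[:, 6:9] = True
        block[6:9, :] = True  # plus sign: area 81, center-hull area 124
        conv = shape_scores(np.column_stack(np.nonzero(block)))[3]
        assert conv == pytest.approx(81 / 124, abs=1e-9)
        assert conv < 0.8

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            shape_scores(np.empty((0, 2)))

    def test_scores_lie_in_unit_interval(self, rng):
        from scipy import ndimage

        for _ in range(20):
            mask = ndimage.binary_dilation(rng.random((16, 16)) < 0.2)
            labels, n = ndimage.label(mask)
            for k in range(1, n + 1):
                _, _, circ, conv, inertia = shape_scores(np.column_stack(np.nonzero(labels == k)))
                assert 0.0 <= circ <= 1.0
                assert 0.0 <= conv <= 1.0
                assert 0.0 <= inertia <= 1.0


class TestDetectBlobs:
    def test_uniform_image_yields_nothing(self):
        assert detect_blobs(np.full((40, 40), 128, dtype=np.uint8), LOOSE) == []

    def test_single_dark_disk_under_loose_column(self):
        # A radius-3.5 disk (37 px) fits the loose 2-40 px^2 area band.
        img = np.full((60, 60), 200, dtype=np.uint8)
        paint_disk(img, 30, 30, 3.5, 40)
        blobs = detect_blobs(img, LOOSE)
        assert len(blobs) == 1
        b = blobs[0]
        assert math.hypot(b.center[0] - 30, b.center[1] - 30) <= 0.5
        assert abs(b.area - math.pi * 3.5**2) <= 0.2 * math.pi * 3.5**2
        assert b.repeatability == len(LOOSE.thresholds())  # core darker than every threshold
        assert b.diameter == pytest.approx(2 * math.sqrt(b.area / math.pi))

    def test_circularity_bound_separates_disk_from_square(self):
        img = np.full((60, 100), 200, dtype=np.uint8)
        paint_disk(img, 30, 20, 3.0, 40)
        img[27:33, 64:70] = 40  # 6x6 square: circularity pi/4 < 0.8
        params = BlobParams(min_circularity=0.8)
        blobs = detect_blobs(img, params)
        assert len(blobs) == 1
        assert blobs[0].center[0] == pytest.approx(20, abs=0.5)
        # both shapes survive once the bound drops below pi/4
        assert len(detect_blobs(img, BlobParams(min_circularity=0.7))) == 2

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        from scipy import ndimage

        params = BlobParams(
            min_threshold=80,
            max_threshold=160,
            threshold_step=8,
            min_repeatability=2,
            min_area=2,
            max_area=200,
            min_circularity=0.2,
            min_convexity=0.2,
            min_inertia_ratio=0.2,
            min_dist_between_blobs=8.0,
        )
        for _ in range(50):
            img = ndimage.gaussian_filter(rng.random((64, 64)), 2.5)
            img = np.interp(img, (img.min(), img.max()), (40, 220)).astype(np.uint8)
            blobs = detect_blobs(img, params)
            oracle = exhaustive_detect(img, params)
            assert len(blobs) == len(oracle)
            for b, o in zip(blobs, oracle):
                assert b.center == pytest.approx(o["center"], abs=1e-9)
                assert b.area == o["area"]
                assert b.repeatability == o["repeatability"]
                assert b.circularity == pytest.approx(o["circularity"], abs=1e-9)
                assert b.convexity == pytest.approx(o["convexity"], abs=1e-9)
                assert b.inertia_ratio == pytest.approx(o["inertia_ratio"], abs=1e-9)

    def test_raising_repeatability_never_adds_blobs(self):
        img = np.full((80, 80), 200, dtype=np.uint8)
        paint_disk(img, 20, 20, 3.0, 40)
        paint_disk(img, 60, 60, 2.5, 90)  # fainter: fewer thresholds
        centers = {}
        for rep in (2, 4, 8, 16, 21):
            blobs = detect_blobs(img, BlobParams(min_repeatability=rep))
            centers[rep] = {b.center for b in blobs}
        for lo, hi in zip((2, 4, 8, 16), (4, 8, 16, 21)):
            assert centers[hi] <= centers[lo]

    def test_widening_area_band_never_removes_blobs(self):
        img = np.full((80, 80), 200, dtype=np.uint8)
        paint_disk(img, 20, 20, 2.0, 40)
        paint_disk(img, 55, 55, 3.5, 40)
        narrow = {b.center for b in detect_blobs(img, BlobParams(min_area=10, max_area=30))}
        wide = {b.center for b in detect_blobs(img, BlobParams(min_area=2, max_area=60))}
        assert narrow <= wide
        assert len(wide) == 2

    def test_translation_equivariance(self):
        img = np.full((70, 70), 200, dtype=np.uint8)
        paint_disk(img, 25, 22, 3.0, 40)
        shifted = np.roll(np.roll(img, 7, axis=0), 11, axis=1)
        ref = detect_blobs(img, LOOSE)
        moved = detect_blobs(shifted, LOOSE)
        assert len(ref) == len(moved) == 1
        assert moved[0].center[0] == pytest.approx(ref[0].center[0] + 11, abs=1e-9)
        assert moved[0].center[1] == pytest.approx(ref[0].center[1] + 7, abs=1e-9)

    def test_planted_disk_recovery_many_seeded_scenes(self):
        # radii 2-5 px, contrast >= 80 gray levels, 10 disks per scene
        matched = BlobParams(
            min_threshold=120,
            max_threshold=190,
            threshold_step=5,
            min_repeatability=4,
            min_area=8,
            max_area=120,
            min_circularity=0.3,
            min_convexity=0.3,
            min_inertia_ratio=0.3,
            min_dist_between_blobs=8.0,
        )
        tp = fp = fn = 0
        for seed in range(50):
            srng = np.random.default_rng([777, seed])
            img = np.full((128, 128), 200, dtype=np.uint8)
            centers = []
            while len(centers) < 10:
                cy, cx = srng.uniform(10, 118, size=2)
                if all(math.hypot(cy - y, cx - x) >= 16 for y, x in centers):
                    centers.append((cy, cx))
            for cy, cx in centers:
                rr, cc = np.mgrid[0:128, 0:128]
                r = srng.uniform(2.0, 5.0)
                img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r * r] = int(srng.uniform(60, 115))
            found = detect_blobs(img, matched)
            used = set()
            for cy, cx in centers:
                hit = None
                for i, b in enumerate(found):
                    if i not in used and math.hypot(b.center[1] - cy, b.center[0] - cx) <= 2.5:
                        hit = i
                        break
                if hit is None:
                    fn += 1
                else:
                    used.add(hit)
                    tp += 1
            fp += len(found) - len(used)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError):
            detect_blobs(np.zeros((4, 4, 3), dtype=np.uint8), LOOSE)


class TestBlobParams:
    def test_threshold_ladder_is_half_open(self):
        assert len(BlobParams().thresholds()) == 20
        assert BlobParams().thresholds()[-1] == 98

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_threshold": 100, "max_threshold": 60},
            {"threshold_step": 0},
            {"min_repeatability": 0},
            {"min_area": 0},
            {"min_area": 50, "max_area": 10},
            {"min_circularity": 1.5},
            {"max_aberration": -1},
            {"polarity": "sideways"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BlobParams(**kwargs)


class TestDetectByRegion:
    def _region_map(self, shape):
        region = np.zeros(shape, dtype=np.uint8)
        region[:, : shape[1] // 2] = CENTER
        region[:, shape[1] // 2 :] = MARGIN
        return region

    def test_blob_carries_its_region(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        paint_disk(img, 30, 45, 3.0, 40)
        region = np.zeros((60, 60), dtype=np.uint8)
        region[:, :] = TIP
        blobs = detect_blobs_by_region(img, region, {"tip": LOOSE})
        assert [b.region for b in blobs] == ["tip"]

    def test_elongated_dash_rejected_in_center_but_kept_at_margin(self):
        img = np.full((60, 120), 200, dtype=np.uint8)
        rr, cc = np.mgrid[0:60, 0:120]
        # identical elongated ellipses (approx 3x4.2 half-axes) in each half
        for cx in (30, 90):
            img[((rr - 30) / 4.2) ** 2 + ((cc - cx) / 3.0) ** 2 <= 1.0] = 40
        region = self._region_map((60, 120))
        blobs = detect_blobs_by_region(img, region, {"root_center": TIGHT, "margin": LOOSE})
        assert [b.region for b in blobs] == ["margin"]
        assert blobs[0].center[0] == pytest.approx(90, abs=1.0)

    def test_background_centered_blobs_dropped(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        paint_disk(img, 30, 30, 3.0, 40)
        region = np.zeros((60, 60), dtype=np.uint8)  # all background
        assert detect_blobs_by_region(img, region, {"margin": LOOSE}) == []

    def test_missing_region_params_raise(self):
        region = np.full((10, 10), TIP, dtype=np.uint8)
        with pytest.raises(KeyError):
            detect_blobs_by_region(np.zeros((10, 10), dtype=np.uint8), region, {"margin": LOOSE})

    def test_root_and_center_fall_back_to_shared_block(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        paint_disk(img, 20, 20, 3.0, 40)
        region = np.full((40, 40), CENTER, dtype=np.uint8)
        blobs = detect_blobs_by_region(img, region, {"root_center": LOOSE})
        assert [b.region for b in blobs] == ["center"]

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            detect_blobs_by_region(
                np.zeros((10, 10), dtype=np.uint8),
                np.zeros((12, 10), dtype=np.uint8),
                {"margin": LOOSE},
            )
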