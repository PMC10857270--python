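"""ROI preprocessing: forehead construction, hull masking, crop/resize/normalize."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsevit import add_forehead_points, crop_resize_normalize, mask_face
from pulsevit.roi import IDENTITY_MEAN, IDENTITY_STD, REGION_COUNTS, LandmarkSet


def random_landmarks68(rng, lo=5.0, hi=55.0) -> np.ndarray:
    return rng.uniform(lo, hi, size=(68, 2))


class TestForeheadPoints:
    def test_stated_elevation_arithmetic(self, rng):
        pts = random_landmarks68(rng)
        pts[:, 1] = np.clip(pts[:, 1], 10, 90)
        # place eyebrow extremes and a known bounding box height
        pts[17] = (10.0, 40.0)
        pts[26] = (60.0, 40.0)
        pts[18:26, 0] = 35.0  # keep extremes at indices 17 and 26
        pts[0, 1], pts[8, 1] = 5.0, 85.0  # bbox height 80
        out = add_forehead_points(pts, k=0.25)
        assert np.allclose(out.points[68], (10.0, 20.0))
        assert np.allclose(out.points[69], (60.0, 20.0))

    def test_k_zero_coincides_with_eyebrow_extremes(self, rng):
        pts = random_landmarks68(rng)
        out = add_forehead_points(pts, k=0.0)
        brows = pts[17:27]
        assert np.allclose(out.points[68], brows[np.argmin(brows[:, 0])])
        assert np.allclose(out.points[69], brows[np.argmax(brows[:, 0])])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_always_70_points_with_first_68_unchanged(self, seed):
        pts = random_landmarks68(np.random.default_rng(seed))
        out = add_forehead_points(pts)
        assert out.points.shape == (70, 2)
        assert np.array_equal(out.points[:68], pts)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            add_forehead_points(rng.uniform(0, 1, (67, 2)))
        flat = np.column_stack([np.linspace(0, 10, 68), np.full(68, 5.0)])
        with pytest.raises(ValueError):
            add_forehead_points(flat)  # zero-height bounding box

    def test_region_schema_counts_sum_to_68(self):
        assert sum(REGION_COUNTS.values()) == 68
        out = add_forehead_points(random_landmarks68(np.random.default_rng(0)))
        assert len(out.region_index["forehead"]) == 2


def brute_force_inside(pts: np.ndarray, h: int, w: int) -> np.ndarray:
    """Independent oracle: shapely convex hull + boundary-inclusive covers."""
    from shapely.geometry import MultiPoint, Point
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = hull.covers(Point(c, r))
    return out


class TestMaskFace:
    def test_hull_covering_frame_keeps_everything(self, rng):
        frame = rng.integers(1, 255, (16, 16, 3), dtype=np.uint8)
        pts = np.array([(-5.0, -5.0), (20.0, -5.0), (20.0, 20.0), (-5.0, 20.0)]
                       + [(8.0, 8.0)] * 66)
        assert np.array_equal(mask_face(frame, pts), frame)

    def test_pixel_outside_hull_is_zeroed(self, rng):
        frame = rng.integers(1, 255, (16, 16, 3), dtype=np.uint8)
        pts = np.vstack([np.random.default_rng(1).uniform(4, 12, (70, 2))])
        masked = mask_face(frame, pts)
        assert np.array_equal(masked[0, 0], (0, 0, 0))  # corner far outside

    def test_agrees_with_brute_force_point_in_polygon(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            frame = rng.integers(1, 255, (16, 16, 3), dtype=np.uint8)
            pts = rng.uniform(-2, 18, (70, 2))
            masked = mask_face(frame, pts)
            inside = brute_force_inside(pts, 16, 16)
            expected = np.where(inside[..., None], frame, 0)
            assert np.array_equal(masked, expected)

    def test_masking_is_idempotent(self, rng):
        frame = rng.integers(1, 255, (24, 24, 3), dtype=np.uint8)
        pts = rng.uniform(2, 22, (70, 2))
        once = mask_face(frame, pts)
        assert np.array_equal(mask_face(once, pts), once)

    def test_inside_mean_invariant_to_outside_pixels(self, rng):
        frame = rng.integers(1, 255, (24, 24, 3), dtype=np.uint8)
        pts = rng.uniform(6, 18, (70, 2))
        masked1 = mask_face(frame, pts)
        tampered = frame.copy()
        outside = ~np.any(masked1 != 0, axis=2)
        tampered[outside] = rng.integers(0, 255, (int(outside.sum()), 3))
        masked2 = mask_face(tampered, pts)
        assert np.array_equal(masked1, masked2)

    def test_collinear_points_rejected(self, rng):
        frame = rng.integers(1, 255, (16, 16, 3), dtype=np.uint8)
        pts = np.column_stack([np.linspace(1, 14, 70), np.linspace(1, 14, 70)])
        with pytest.raises(ValueError):
            mask_face(frame, pts)


class TestCropResizeNormalize:
    def test_full_frame_identity_constants_is_scaling_only(self, rng):
        frame = rng.integers(1, 255, (224, 224, 3), dtype=np.uint8)
        pf = crop_resize_normalize(frame, mean=IDENTITY_MEAN, std=IDENTITY_STD)
        assert np.allclose(pf.image, frame / 255.0, atol=1e-6)
        assert pf.mask_fraction == 1.0

    def test_centered_padding_arithmetic(self):
        frame = np.zeros((120, 80, 3), dtype=np.uint8)
        frame[10:110, 15:65] = 200  # nonzero region 100 x 50
        pf = crop_resize_normalize(frame, size=100, mean=IDENTITY_MEAN, std=IDENTITY_STD)
        # intermediate square is 100x100 -> no resize; 25-pixel zero bands
        assert np.all(pf.image[:, :25] == 0) and np.all(pf.image[:, 75:] == 0)
        assert np.all(pf.image[:, 25:75] > 0)

    def test_inverse_normalization_round_trip(self, rng):
        frame = np.zeros((40, 40, 3), dtype=np.uint8)
        frame[5:30, 8:35] = rng.integers(1, 255, (25, 27, 3))
        pf = crop_resize_normalize(frame, size=32)
        from pulsevit.roi import IMAGENET_MEAN, IMAGENET_STD
        recovered = pf.image * np.asarray(IMAGENET_STD) + np.asarray(IMAGENET_MEAN)
        pf01 = crop_resize_normalize(frame, size=32, mean=IDENTITY_MEAN, std=IDENTITY_STD)
        assert np.allclose(recovered, pf01.image, atol=1e-5)

    @pytest.mark.parametrize("shape", [(30, 50), (128, 64), (224, 224)])
    def test_output_shape_is_always_square_target(self, shape, rng):
        frame = np.zeros((*shape, 3), dtype=np.uint8)
        frame[2:shape[0] - 2, 2:shape[1] - 2] = rng.integers(1, 255, (shape[0] - 4, shape[1] - 4, 3))
        assert crop_resize_normalize(frame).image.shape == (224, 224, 3)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            crop_resize_normalize(np.zeros((10, 10, 3), dtype=np.uint8))


def test_landmark_set_validation(rng):
    with pytest.raises(ValueError):
        LandmarkSet(points=rng.uniform(0, 1, (69, 2)))
    bad = rng.uniform(0, 1, (70, 2))
    bad[3, 0] = np.nan
    with pytest.raises(ValueError):
        LandmarkSet(points=bad)
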