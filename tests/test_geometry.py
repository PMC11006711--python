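"""Alignment, cropping and ocular-ROI geometry."""

import json

import numpy as np
import pytest

from nutriface.geometry import (
    ALIGNED_SIDE,
    DegenerateGeometryError,
    FaceImage,
    GeometryError,
    Landmark,
    LandmarkSet,
    Rect,
    align_and_crop,
    align_face,
    alignment_angle,
    crop_and_normalize,
    eye_centers,
    eye_roi,
    load_landmarks,
    mask_eye_region,
    rotate_points,
    save_landmarks,
)
from nutriface.synthetic import SimConfig, generate_face


def _set_points(base: np.ndarray, sl, pts) -> LandmarkSet:
    arr = base.copy()
    arr[sl] = pts
    return LandmarkSet(arr)


class TestEyeCenters:
    def test_identity_when_all_points_coincide(self, template_landmarks):
        lms = _set_points(template_landmarks, slice(36, 42), [(10.0, 20.0)] * 6)
        lc, _ = eye_centers(lms)
        assert (lc.x, lc.y) == (10.0, 20.0)

    def test_regular_hexagon_centers_on_its_centroid(self, template_landmarks):
        ang = np.radians(np.arange(6) * 60.0)
        hexa = np.stack([50 + 7 * np.cos(ang), 60 + 7 * np.sin(ang)], axis=1)
        lms = _set_points(template_landmarks, slice(36, 42), hexa)
        lc, _ = eye_centers(lms)
        assert np.allclose([lc.x, lc.y], [50, 60])

    def test_matches_summation_oracle_on_random_points(self, template_landmarks):
        rng = np.random.default_rng(3)
        pts = rng.uniform(10, 60, size=(6, 2))
        lms = _set_points(template_landmarks, slice(36, 42), pts)
        lc, _ = eye_centers(lms)
        # independent componentwise summation
        sx = sum(p[0] for p in pts) / 6.0
        sy = sum(p[1] for p in pts) / 6.0
        assert np.allclose([lc.x, lc.y], [sx, sy], atol=1e-12)

    def test_wrong_landmark_count_rejected(self):
        with pytest.raises(GeometryError):
            LandmarkSet(np.zeros((67, 2)))


class TestAlignmentAngle:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            ((100, 120), (160, 120), 0.0),
            ((0, 0), (10, 10), 45.0),
            ((100, 120), (160, 100), np.degrees(np.arctan2(-20, 60))),
        ],
    )
    def test_reference_angles(self, left, right, expected):
        got = alignment_angle(Landmark(*left), Landmark(*right))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_coincident_centers_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            alignment_angle(Landmark(5, 5), Landmark(5, 5))


class TestAlignFace:
    def test_zero_angle_is_identity(self, clean_config):
        img, lms = generate_face(0.2, clean_config, np.random.default_rng(0))
        out_img, out_lms = align_face(img, lms)
        assert np.allclose(out_lms.points, lms.points, atol=1e-9)
        assert np.allclose(out_img.pixels, img.to_gray(), atol=1e-6)

    def test_tilted_face_becomes_horizontal(self):
        cfg = SimConfig(noise_sd=0.0, max_rotation_deg=45.0, jitter=0.0,
                        scale_jitter=0.0)
        img, lms = generate_face(0.2, cfg, np.random.default_rng(5))
        _, out_lms = align_face(img, lms)
        lc, rc = eye_centers(out_lms)
        assert abs(lc.y - rc.y) < 1.5

    def test_landmarks_match_rotation_matrix_oracle(self, template_landmarks):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = template_landmarks + rng.normal(0, 2, size=(68, 2))
            theta = rng.uniform(-80, 80)
            c = pts.mean(axis=0)
            got = rotate_points(pts, theta, c)
            # independent closed form: x' = c + cos, y' = ... (y-down R(-theta))
            t = np.radians(theta)
            dx, dy = (pts - c).T
            exp = np.stack(
                [np.cos(t) * dx + np.sin(t) * dy,
                 -np.sin(t) * dx + np.cos(t) * dy], axis=1
            ) + c
            assert np.max(np.abs(got - exp)) < 1e-6

    def test_alignment_is_idempotent(self):
        cfg = SimConfig(noise_sd=0.0, max_rotation_deg=30.0)
        img, lms = generate_face(0.5, cfg, np.random.default_rng(8))
        img1, lms1 = align_face(img, lms)
        lc, rc = eye_centers(lms1)
        assert abs(alignment_angle(lc, rc)) < 0.1


class TestCropAndNormalize:
    def _landmarks_with_D(self, base: np.ndarray, D: float) -> LandmarkSet:
        """Place eyes and mouth so the eye-midpoint to mouth distance is D."""
        arr = base.copy()
        arr[36:42] = np.array([140.0, 100.0]) + (arr[36:42] - arr[36:42].mean(axis=0))
        arr[42:48] = np.array([180.0, 100.0]) + (arr[42:48] - arr[42:48].mean(axis=0))
        arr[48:68] = np.array([160.0, 100.0 + D]) + (arr[48:68] - arr[48:68].mean(axis=0))
        return LandmarkSet(arr)

    def test_output_is_always_256(self, template_landmarks):
        rng = np.random.default_rng(2)
        for side in (64, 120, 300, 512):
            img = FaceImage(rng.uniform(size=(side, side)))
            lms = LandmarkSet(template_landmarks * (side / 320.0))
            face = crop_and_normalize(img, lms)
            assert face.image.shape == (ALIGNED_SIDE, ALIGNED_SIDE)

    def test_band_heights_for_D_100(self, template_landmarks):
        lms = self._landmarks_with_D(template_landmarks, 100.0)
        img = FaceImage(np.full((320, 320), 0.5))
        face = crop_and_normalize(img, lms)
        rect = face.crop_rect
        assert rect.height == pytest.approx(100.0)
        assert 0.4 * rect.height == pytest.approx(40.0)      # middle band
        assert 0.3 * rect.height == pytest.approx(30.0)      # top and bottom bands
        assert rect.width == pytest.approx(
            0.3 * rect.height + 0.4 * rect.height + 0.3 * rect.height
        )

    def test_degenerate_geometry_rejected(self, template_landmarks):
        arr = template_landmarks.copy()
        # mouth centroid on the eye midpoint
        eye_mid = (arr[36:42].mean(axis=0) + arr[42:48].mean(axis=0)) / 2
        arr[48:68] = eye_mid + (arr[48:68] - arr[48:68].mean(axis=0)) * 0.0
        img = FaceImage(np.full((320, 320), 0.5))
        with pytest.raises(DegenerateGeometryError):
            crop_and_normalize(img, LandmarkSet(arr))

    def test_full_alignment_keeps_eyes_horizontal(self):
        cfg = SimConfig(noise_sd=0.0, max_rotation_deg=20.0)
        img, lms = generate_face(0.3, cfg, np.random.default_rng(3))
        face = align_and_crop(img, lms)
        lc, rc = eye_centers(face.landmarks)
        assert abs(lc.y - rc.y) < 1.5


class TestEyeRoi:
    def test_direct_construction(self, template_landmarks):
        arr = template_landmarks.copy()
        arr[17:22, 0] = np.linspace(60, 110, 5)    # left brow x
        arr[22:27, 0] = np.linspace(150, 196, 5)   # right brow x
        arr[17:27, 1] = np.linspace(80, 95, 10)    # brow ys, min 80
        arr[29] = (128.0, 140.0)                   # third nose point
        roi = eye_roi(LandmarkSet(arr))
        assert (roi.left, roi.top, roi.right, roi.bottom) == (60, 80, 196, 140)

    def test_mirror_equivariance(self, template_landmarks):
        roi = eye_roi(LandmarkSet(template_landmarks))
        W = 320.0
        mirrored = template_landmarks.copy()
        mirrored[:, 0] = W - mirrored[:, 0]
        # mirroring swaps the left/right groups; rebuild a valid 68-set
        swapped = mirrored.copy()
        swapped[17:22], swapped[22:27] = mirrored[22:27][::-1], mirrored[17:22][::-1]
        swapped[36:42], swapped[42:48] = mirrored[42:48], mirrored[36:42]
        roi_m = eye_roi(LandmarkSet(swapped))
        assert roi_m.left == pytest.approx(W - roi.right)
        assert roi_m.right == pytest.approx(W - roi.left)
        assert (roi_m.top, roi_m.bottom) == (roi.top, roi.bottom)

    def test_matches_min_max_scan_oracle(self, template_landmarks):
        rng = np.random.default_rng(9)
        for _ in range(50):
            arr = template_landmarks + rng.normal(0, 3, size=(68, 2))
            lms = LandmarkSet(arr)
            roi = eye_roi(lms)
            # brute-force extrema scan
            assert roi.left == min(arr[i, 0] for i in range(17, 22))
            assert roi.right == max(arr[i, 0] for i in range(22, 27))
            assert roi.top == min(arr[i, 1] for i in range(17, 27))
            assert roi.bottom == arr[29, 1]


class TestMaskEyeRegion:
    def _face(self, fill=1.0):
        from nutriface.geometry import AlignedFace

        lms = LandmarkSet(_scaled_template())
        return AlignedFace(image=np.full((256, 256), fill), landmarks=lms)

    def test_single_pixel_roi(self):
        face = self._face()
        out = mask_eye_region(face, Rect(10, 10, 11, 11))
        assert out.image[10, 10] == 0.0
        assert out.image.sum() == 256 * 256 - 1

    def test_quarter_mask_mean(self):
        face = self._face(1.0)
        out = mask_eye_region(face, Rect(0, 0, 128, 128))
        assert out.image.mean() == pytest.approx(0.75)

    def test_idempotent(self):
        face = self._face()
        roi = Rect(30, 40, 90, 80)
        once = mask_eye_region(face, roi)
        twice = mask_eye_region(once, roi)
        assert np.array_equal(once.image, twice.image)


def _scaled_template():
    from nutriface.synthetic import _template_landmarks

    return _template_landmarks() * 256.0


class TestLandmarkIO:
    def test_json_roundtrip(self, tmp_path, landmarks68):
        p = tmp_path / "lm.json"
        save_landmarks(landmarks68, p)
        back = load_landmarks(p)
        assert np.allclose(back.points, landmarks68.points)

    def test_csv_reader_and_validation(self, tmp_path, landmarks68):
        import pandas as pd

        p = tmp_path / "lm.csv"
        pd.DataFrame(
            {"index": range(68),
             "x": landmarks68.points[:, 0],
             "y": landmarks68.points[:, 1]}
        ).to_csv(p, index=False)
        back = load_landmarks(str(p))
        assert np.allclose(back.points, landmarks68.points)

        bad = tmp_path / "bad.csv"
        pd.DataFrame({"index": range(5), "x": range(5), "y": range(5)}).to_csv(bad, index=False)
        with pytest.raises(GeometryError):
            load_landmarks(str(bad))

    def test_json_wrong_count_rejected(self, tmp_path):
        p = tmp_path / "short.json"
        p.write_text(json.dumps([[1, 2]] * 10))
        with pytest.raises(GeometryError):
            load_landmarks(p)
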