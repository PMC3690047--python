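"""Pin-hole geometry: depth, fusion, distance-invariant area, volume."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitglove import vision
from fruitglove.simulate import SceneSpec, render_scene
from fruitglove.vision import CameraModel


class TestFocalAndFov:
    def test_right_angle_fov(self):
        assert vision.focal_from_fov(2, 90.0) == pytest.approx(1.0)

    def test_vga_camera(self):
        f = vision.focal_from_fov(640, 48.0)
        assert f == pytest.approx(320 / math.tan(math.radians(24)), rel=1e-12)

    def test_monotone_decreasing_in_fov(self):
        fovs = np.linspace(10, 170, 30)
        fs = [vision.focal_from_fov(640, fov) for fov in fovs]
        assert np.all(np.diff(fs) < 0)

    def test_invalid_fov(self):
        for bad in (0.0, 180.0, -5.0):
            with pytest.raises(vision.GeometryError):
                vision.focal_from_fov(640, bad)

    def test_camera_round_trips_fov(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        assert cam.fov_deg == pytest.approx(48.0)


class TestDepth:
    def test_stereo_depth_hand_value(self):
        cam = CameraModel(width_px=640, height_px=480, f_px=100.0, baseline_cm=2.5)
        assert vision.stereo_depth(50.0, 25.0, cam) == pytest.approx(10.0)

    def test_doubling_disparity_halves_depth(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        z1 = vision.stereo_depth(40.0, 20.0, cam)
        z2 = vision.stereo_depth(60.0, 20.0, cam)
        assert z2 == pytest.approx(z1 / 2)

    @given(st.floats(0.1, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_depth_disparity_round_trip(self, z):
        cam = CameraModel.from_fov(640, 480, 48.0)
        d = vision.disparity_for_depth(z, cam)
        assert vision.stereo_depth(d, 0.0, cam) == pytest.approx(z, rel=1e-12)

    def test_zero_disparity_rejected(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        with pytest.raises(vision.GeometryError):
            vision.stereo_depth(10.0, 10.0, cam)

    def test_disparity_vanishes_at_infinity(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        assert vision.disparity_for_depth(1e9, cam) == pytest.approx(0.0, abs=1e-3)

    def test_laser_depth_reliability_window(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        near = vision.laser_depth(cam.f_px * cam.baseline_cm / 5.0, cam)
        assert near.Z_cm == pytest.approx(5.0)
        assert near.reliable
        far = vision.laser_depth(cam.f_px * cam.baseline_cm / 10.0, cam)
        assert far.Z_cm == pytest.approx(10.0)
        assert not far.reliable

    def test_laser_depth_from_rendered_scene(self, small_camera):
        # dot offset in a rendered scene inverts back to the scene depth
        # within pixel quantization
        scene = render_scene(
            SceneSpec(radius_cm=3.0, z_cm=6.0, camera=small_camera, dot_radius_px=1)
        )
        from fruitglove.segmentation import detect_laser_dot

        dot = detect_laser_dot(scene.rgb)
        offset = dot[0] - small_camera.principal_point[0]
        est = vision.laser_depth(offset, small_camera)
        quantization = 6.0 / offset * 1.0  # dZ for one pixel of offset error
        assert est.Z_cm == pytest.approx(6.0, abs=2 * quantization)
        assert est.reliable


class TestMergeNir:
    def test_zero_baseline_is_channel_concatenation(self):
        cam = CameraModel(width_px=16, height_px=8, f_px=10.0, baseline_cm=0.0)
        rng = np.random.default_rng(0)
        vis = rng.integers(0, 255, (8, 16, 3)).astype(np.uint8)
        nir = rng.integers(0, 255, (8, 16)).astype(np.uint8)
        fused = vision.merge_nir(vis, nir, Z=5.0, cam=cam)
        assert np.array_equal(fused.rgbi[..., :3], vis.astype(float))
        assert fused.rgbi[..., 3] == pytest.approx(nir.astype(float))
        assert not fused.oob.any()

    def test_shift_vanishes_at_large_depth(self):
        cam = CameraModel(width_px=16, height_px=8, f_px=10.0, baseline_cm=2.5)
        nir = np.tile(np.arange(16, dtype=float), (8, 1))
        vis = np.zeros((8, 16, 3), dtype=np.uint8)
        fused = vision.merge_nir(vis, nir, Z=1e9, cam=cam)
        assert fused.rgbi[..., 3] == pytest.approx(nir, abs=1e-6)

    def test_simulated_pair_aligns_after_fusion(self, small_camera):
        # scene with known NIR disparity of 12 px: fused I channel overlaps
        # the RGB fruit mask almost perfectly
        z = small_camera.f_px * small_camera.baseline_cm / 12.0
        scene = render_scene(SceneSpec(radius_cm=3.0, z_cm=z, camera=small_camera, nir=True))
        fused = vision.merge_nir(scene.rgb, scene.nir, z, small_camera)
        aligned = fused.rgbi[..., 3] > 100
        inter = np.logical_and(aligned, scene.mask).sum()
        union = np.logical_or(aligned, scene.mask).sum()
        assert inter / union >= 0.98

    def test_dimension_mismatch(self):
        cam = CameraModel(width_px=16, height_px=8, f_px=10.0)
        with pytest.raises(vision.GeometryError):
            vision.merge_nir(np.zeros((8, 16, 3)), np.zeros((8, 15)), 5.0, cam)


class TestAreaAndVolume:
    def test_invariant_area_hand_values(self):
        assert vision.distance_invariant_area(1000.0, 10.0, 100.0) == pytest.approx(10.0)
        # Z numerically equal to f: t equals the raw pixel count
        assert vision.distance_invariant_area(1234.0, 50.0, 50.0) == pytest.approx(1234.0)

    def test_invariance_across_depth(self, small_camera):
        # the same 3 cm fruit rendered at two depths yields the same t
        ts = []
        for z in (5.0, 7.0):
            scene = render_scene(SceneSpec(radius_cm=3.0, z_cm=z, camera=small_camera))
            a_ci = scene.truth["a_ci_px"]
            ts.append(vision.distance_invariant_area(a_ci, z, small_camera.f_px))
        assert abs(ts[0] - ts[1]) / ts[1] < 0.02

    def test_area_poly_evaluation(self):
        est = vision.area_to_cm2(1000.0)
        expected = float(np.polyval(vision.AREA_POLY_DEFAULT, 1000.0))
        assert est.area_cm2 == pytest.approx(expected)
        assert not est.clamped

    def test_area_poly_clamps_below_calibrated_span(self):
        est = vision.area_to_cm2(0.0)
        assert est.area_cm2 == 0.0
        assert est.clamped  # raw value is the negative constant term

    def test_area_poly_monotone_over_calibrated_range(self):
        # the cubic's negative leading term turns it over near t ~ 2.1e4
        # (~50 cm2), the top of the ten-circle calibration span
        t = np.linspace(0, 1.8e4, 5000)
        vals = np.polyval(vision.AREA_POLY_DEFAULT, t)
        assert np.all(np.diff(vals) > 0)

    def test_identity_poly_passthrough(self):
        est = vision.area_to_cm2(28.27, vision.AREA_POLY_IDENTITY)
        assert est.area_cm2 == pytest.approx(28.27)

    @pytest.mark.parametrize(
        "area, radius, volume",
        [
            (math.pi, 1.0, 4 * math.pi / 3),
            (0.0, 0.0, 0.0),
            (4 * math.pi, 2.0, 32 * math.pi / 3),
        ],
    )
    def test_radius_and_volume(self, area, radius, volume):
        assert vision.radius_from_area(area) == pytest.approx(radius)
        assert vision.sphere_volume(area) == pytest.approx(volume)

    @given(st.floats(0.01, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_radius_area_consistency(self, area):
        r = vision.radius_from_area(area)
        assert math.pi * r * r == pytest.approx(area, rel=1e-12)

    def test_volume_strictly_increasing(self):
        areas = np.linspace(0.1, 100, 200)
        vols = [vision.sphere_volume(a) for a in areas]
        assert np.all(np.diff(vols) > 0)

    def test_negative_area_rejected(self):
        with pytest.raises(vision.GeometryError):
            vision.radius_from_area(-1.0)


class TestVisibleDiameter:
    def test_vga_at_31cm(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        d = vision.max_visible_diameter(31.0, cam)
        assert round(d) == 28
        assert d == pytest.approx(2 * 31 * math.tan(math.radians(24)), rel=1e-12)

    def test_zero_depth(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        assert vision.max_visible_diameter(0.0, cam) == 0.0

    def test_linear_in_depth(self):
        cam = CameraModel.from_fov(640, 480, 48.0)
        d10 = vision.max_visible_diameter(10.0, cam)
        d20 = vision.max_visible_diameter(20.0, cam)
        assert d20 == pytest.approx(2 * d10)
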