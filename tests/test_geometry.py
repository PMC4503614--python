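"""Closed-form estimator tests against hand-evaluated oracle values and
exactness properties of the projection geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from laserline import (
    CameraIntrinsics,
    DegenerateGeometryError,
    ImageMeasurements,
    LaserRig,
    camera_height,
    camera_height_simple,
    estimate_pose,
    ground_area,
    ground_area_simple,
    ground_grid_overlay,
    ground_length,
    ground_length_simple,
    perspective_cotangents,
    seabed_slope,
    vanishing_point,
)
from laserline import forward, report

from conftest import make_scene, random_scene, reference_rows


class TestValidationStill:
    """The in situ validation still: every estimate frozen against an
    independent hand evaluation of the closed forms."""

    def test_pose(self, validation_measurements, hd_camera):
        pose = estimate_pose(validation_measurements, hd_camera)
        assert pose.cos_tilt == pytest.approx(0.9459400187951472, rel=1e-12)
        assert pose.tilt_deg == pytest.approx(18.925691490382174, rel=1e-12)
        assert pose.cos_pan == pytest.approx(0.9998450547663096, rel=1e-12)
        assert pose.pan_deg == pytest.approx(-1.00863108540472, rel=1e-12)

    def test_vanishing_point_offsets(self, validation_measurements, hd_camera):
        pose = estimate_pose(validation_measurements, hd_camera)
        # camera pans left (gamma < 0): vanishing point right of center
        assert pose.vp_u == pytest.approx(25.2962962963, abs=1e-6)
        assert pose.vp_v == pytest.approx(517.8148148148, abs=1e-6)

    def test_ground_length(self, validation_measurements, hd_camera, survey_rig):
        length = ground_length(validation_measurements, hd_camera, survey_rig)
        assert length == pytest.approx(106.41230864171267, rel=1e-12)
        assert round(length, 1) == 106.4

    def test_ground_area(self, validation_measurements, hd_camera, survey_rig):
        area = ground_area(validation_measurements, hd_camera, survey_rig)
        assert area == pytest.approx(106.41230864171267 * 67.0, rel=1e-12)

    def test_perspective_cotangents(self, validation_measurements, hd_camera):
        cot1, cot2 = perspective_cotangents(validation_measurements, hd_camera)
        assert cot1 == pytest.approx(0.4040515249537728, rel=1e-12)
        assert cot2 == pytest.approx(0.2253364273780656, rel=1e-12)

    def test_camera_height(self, validation_measurements, hd_camera, survey_rig):
        height = camera_height(validation_measurements, hd_camera, survey_rig)
        assert round(height, 1) == 100.7


class TestPoseEdgeCases:
    def test_zero_bracket_means_level_camera(self, hd_camera):
        # m0/M - 1/2 + (n'/(n1+n2))*(m/M) = 0.375 - 0.5 + 0.125 = 0
        meas = ImageMeasurements(
            n_prime=100, n_dprime=50, n0=450, n1=50, n2=50, m0=300, m=100
        )
        pose = estimate_pose(meas, hd_camera)
        assert pose.cos_tilt == 1.0
        assert pose.tilt_rad == 0.0

    def test_centered_vanishing_vertical_means_zero_pan(self, hd_camera):
        # n0/N + (n1/(n1+n2))*(n'/N) = 1/2 exactly
        meas = ImageMeasurements(
            n_prime=200, n_dprime=100, n0=540, n1=100, n2=100, m0=700, m=200
        )
        pose = estimate_pose(meas, hd_camera)
        assert pose.cos_pan == 1.0
        assert pose.pan_rad == 0.0

    def test_level_pose_gives_central_vanishing_point(self, hd_camera):
        assert vanishing_point(0.0, 0.0, hd_camera) == (0.0, 0.0)

    def test_vanishing_point_undefined_rejected(self):
        with pytest.raises(ValueError, match="vanishing point undefined"):
            ImageMeasurements(
                n_prime=100, n_dprime=50, n0=0, n1=0, n2=0, m0=100, m=100
            )


class TestLengthAndHeight:
    def test_simple_length_hand_value(self):
        cam = CameraIntrinsics(60.0, 40.0, 1000, 800)
        rig = LaserRig(60.0)
        length = ground_length_simple(400, 200, cam, rig)
        # (400/200 - 1) * (1000/400) * 60 / (2 tan 30)
        assert length == pytest.approx(2.5 * 60.0 / (2 * math.tan(math.radians(30))),
                                       rel=1e-12)
        assert length == pytest.approx(129.9038105676658, rel=1e-12)
        assert ground_area_simple(400, 200, cam, rig) == pytest.approx(
            length * 60.0, rel=1e-12
        )

    def test_coincident_rows_give_zero_length(self, hd_camera, survey_rig):
        assert ground_length_simple(400, 400, hd_camera, survey_rig) == 0.0

    def test_far_row_wider_rejected(self, hd_camera, survey_rig):
        with pytest.raises(DegenerateGeometryError, match="narrower"):
            ground_length_simple(200, 300, hd_camera, survey_rig)

    def test_subpixel_row_separation_rejected(self, hd_camera, survey_rig):
        with pytest.raises(DegenerateGeometryError, match="diverges|half a pixel"):
            ground_length_simple(300.2, 300.0, hd_camera, survey_rig)

    def test_simple_height_unit_ratio(self, survey_rig):
        # row one laser-separation below the center recovers h = l
        assert camera_height_simple(-300.0, 300.0, survey_rig) == pytest.approx(
            survey_rig.separation_cm
        )

    def test_height_45_degree_perspective_angles(self, hd_camera, survey_rig):
        # cot(45) + cot(45) = 2  ->  h = l / 2 for a level camera
        m = 100.0
        scale = (
            hd_camera.width_px
            * hd_camera.tan_half_v
            / (hd_camera.height_px * hd_camera.tan_half_h)
        )
        n_side = m * scale  # cot theta = 1 on each side
        meas = ImageMeasurements(
            n_prime=500, n_dprime=250, n0=300,
            n1=n_side, n2=n_side, m0=100, m=m,
        )
        cot1, cot2 = perspective_cotangents(meas, hd_camera)
        assert cot1 == pytest.approx(1.0, rel=1e-12)
        height = (
            survey_rig.separation_cm / (cot1 + cot2)
        )  # level camera: cosines are 1
        assert height == pytest.approx(survey_rig.separation_cm / 2.0, rel=1e-12)

    def test_vertical_line_has_zero_cotangent(self, hd_camera):
        meas = ImageMeasurements(
            n_prime=100, n_dprime=50, n0=500, n1=0, n2=80, m0=100, m=100
        )
        cot1, cot2 = perspective_cotangents(meas, hd_camera)
        assert cot1 == 0.0
        assert cot2 > 0.0

    def test_negative_n1_with_positive_sum_is_valid(self, hd_camera, survey_rig):
        # strong pan: the vanishing-point vertical falls left of both lines
        meas = ImageMeasurements(
            n_prime=100, n_dprime=50, n0=500, n1=-30, n2=80, m0=100, m=100
        )
        assert camera_height(meas, hd_camera, survey_rig) > 0.0


class TestInvariants:
    @given(scale=st.floats(min_value=0.05, max_value=50.0))
    def test_m_invariance(self, scale):
        """Scaling (m, n1, n2) jointly leaves every estimate unchanged:
        only the line slopes enter the closed forms."""
        cam = CameraIntrinsics(50.43, 29.67, 1280, 800)
        rig = LaserRig(67.0)
        base = ImageMeasurements(
            n_prime=312, n_dprime=232, n0=465, n1=52, n2=29, m0=367, m=143
        )
        scaled = ImageMeasurements(
            n_prime=312, n_dprime=232, n0=465,
            n1=52 * scale, n2=29 * scale, m0=367, m=143 * scale,
        )
        pose_a, pose_b = estimate_pose(base, cam), estimate_pose(scaled, cam)
        assert pose_b.tilt_rad == pytest.approx(pose_a.tilt_rad, rel=1e-12)
        assert pose_b.pan_rad == pytest.approx(pose_a.pan_rad, rel=1e-12)
        assert ground_length(scaled, cam, rig) == pytest.approx(
            ground_length(base, cam, rig), rel=1e-12
        )
        assert camera_height(scaled, cam, rig) == pytest.approx(
            camera_height(base, cam, rig), rel=1e-12
        )

    def test_general_reduces_to_simple_at_zero_pose(self, hd_camera, survey_rig):
        """At a level, laser-aligned camera the general closed forms
        equal the simple-case ones exactly."""
        scene = make_scene(hd_camera, tilt_deg=0.0, pan_deg=0.0, height_cm=120.0,
                           left_offset_cm=33.5, right_offset_cm=33.5)
        meas, _ = forward.synthesize_measurements(scene, 700.0, 550.0)
        pose = estimate_pose(meas, hd_camera)
        assert pose.cos_tilt == pytest.approx(1.0, abs=1e-12)
        assert pose.cos_pan == pytest.approx(1.0, abs=1e-12)
        general = ground_length(meas, hd_camera, survey_rig, pose)
        simple = ground_length_simple(
            meas.n_prime, meas.n_dprime, hd_camera, survey_rig
        )
        assert general == pytest.approx(simple, rel=1e-14)
        z_a = (
            hd_camera.height_px / 2.0 - 700.0
        ) * hd_camera.vertical_px_scale
        h_simple = camera_height_simple(z_a, meas.n_prime, survey_rig)
        h_general = camera_height(meas, hd_camera, survey_rig, pose)
        assert h_general == pytest.approx(h_simple, rel=1e-12)

    def test_mirror_symmetry(self, hd_camera, survey_rig):
        """Negating the pan and mirroring the measurements left-right
        leaves L, S, h unchanged and flips the vanishing point's side."""
        scene = make_scene(hd_camera, 20.0, 8.0, 130.0, 30.0, 37.0)
        mirrored = make_scene(hd_camera, 20.0, -8.0, 130.0, 37.0, 30.0)
        near, far = reference_rows(scene)
        meas_a, _ = forward.synthesize_measurements(scene, near, far)
        meas_b, _ = forward.synthesize_measurements(mirrored, near, far)
        # mirroring the raster: u -> N - u
        assert meas_b.n0 == pytest.approx(
            hd_camera.width_px - meas_a.n0 - meas_a.n_prime, rel=1e-9
        )
        assert meas_b.n1 == pytest.approx(meas_a.n2, rel=1e-9)
        pose_a = estimate_pose(meas_a, hd_camera)
        pose_b = estimate_pose(meas_b, hd_camera)
        assert pose_b.pan_rad == pytest.approx(-pose_a.pan_rad, rel=1e-9)
        assert pose_b.vp_u == pytest.approx(-pose_a.vp_u, rel=1e-9)
        assert ground_length(meas_b, hd_camera, survey_rig) == pytest.approx(
            ground_length(meas_a, hd_camera, survey_rig), rel=1e-9
        )
        assert camera_height(meas_b, hd_camera, survey_rig) == pytest.approx(
            camera_height(meas_a, hd_camera, survey_rig), rel=1e-9
        )

    @given(factor=st.floats(min_value=0.2, max_value=5.0))
    def test_length_scales_linearly_area_quadratically_in_l(self, factor):
        cam = CameraIntrinsics(50.43, 29.67, 1280, 800)
        meas = ImageMeasurements(
            n_prime=312, n_dprime=232, n0=465, n1=52, n2=29, m0=367, m=143
        )
        rig_a, rig_b = LaserRig(67.0), LaserRig(67.0 * factor)
        assert ground_length(meas, cam, rig_b) == pytest.approx(
            factor * ground_length(meas, cam, rig_a), rel=1e-12
        )
        assert ground_area(meas, cam, rig_b) == pytest.approx(
            factor**2 * ground_area(meas, cam, rig_a), rel=1e-12
        )

    def test_seabed_slope_arithmetic(self):
        assert seabed_slope(math.radians(18.92), math.radians(18.92)) == 0.0
        assert math.degrees(
            seabed_slope(math.radians(25.0), math.radians(10.0))
        ) == pytest.approx(15.0)


class TestGridOverlay:
    def test_laser_lines_are_grid_members_at_spacing_l(
        self, validation_measurements, hd_camera, survey_rig
    ):
        overlay = ground_grid_overlay(
            validation_measurements, hd_camera, survey_rig,
            lateral_spacing_cm=survey_rig.separation_cm, axial_spacing_cm=50.0,
        )
        meas = validation_measurements
        slopes = sorted(
            (s.u2 - s.u1) / (s.v2 - s.v1) for s in overlay.lateral
        )
        expected_left = -meas.n1 / meas.m
        expected_right = meas.n2 / meas.m
        assert any(s == pytest.approx(expected_left, abs=1e-12) for s in slopes)
        assert any(s == pytest.approx(expected_right, abs=1e-12) for s in slopes)

    def test_axial_rows_have_equal_ground_spacing(self, hd_camera, survey_rig):
        """Back-projecting consecutive overlay rows through the exact
        forward model gives ground separations equal to the requested
        spacing."""
        scene = make_scene(hd_camera, 22.0, 6.0, 140.0, 33.0, 34.0)
        near, far = reference_rows(scene)
        meas, _ = forward.synthesize_measurements(scene, near, far)
        rig = scene.rig()
        overlay = ground_grid_overlay(
            meas, hd_camera, rig, lateral_spacing_cm=20.0, axial_spacing_cm=50.0
        )
        rows = [seg.v1 for seg in overlay.axial]
        assert len(rows) >= 3
        for v_near, v_far in zip(rows, rows[1:]):
            assert forward.row_trace_length(scene, v_near, v_far) == pytest.approx(
                50.0, rel=1e-9
            )

    def test_zero_pose_rows_match_simple_inversion(self, hd_camera, survey_rig):
        """For a level camera the overlay rows invert the simple length
        equation: 1/n grows by spacing * 2 tan(aH/2) / (N l) per row."""
        scene = make_scene(hd_camera, 0.0, 0.0, 120.0, 33.5, 33.5)
        meas, _ = forward.synthesize_measurements(scene, 700.0, 500.0)
        overlay = ground_grid_overlay(
            meas, hd_camera, survey_rig, lateral_spacing_cm=67.0,
            axial_spacing_cm=40.0,
        )
        total = meas.n1 + meas.n2
        v_v = 400.0  # level camera: vanishing point at the image center
        inv_n = [
            meas.m / ((seg.v1 - v_v) * total) for seg in overlay.axial
        ]
        step = 40.0 * 2.0 * hd_camera.tan_half_h / (
            hd_camera.width_px * survey_rig.separation_cm
        )
        increments = np.diff(inv_n)
        assert np.allclose(increments, step, rtol=1e-9)

    def test_rejects_nonpositive_spacing(
        self, validation_measurements, hd_camera, survey_rig
    ):
        with pytest.raises(ValueError, match="positive"):
            ground_grid_overlay(
                validation_measurements, hd_camera, survey_rig, 0.0, 50.0
            )
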