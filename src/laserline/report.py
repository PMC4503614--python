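"""One image in, one report out.

:func:`measure` ties the estimators and the uncertainty propagation
together: pixel measurements + camera + rig → pose, ground length,
area, camera height, their maximal uncertainties, and optionally the
seabed slope when the true camera tilt is supplied by an attitude
sensor.  Reports echo every input and the package version so published
area estimates stay reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from . import geometry, uncertainty
from .exceptions import VanishingPointAtInfinity
from .models import (
    AnnotationSet,
    CameraIntrinsics,
    GroundEstimate,
    ImageMeasurements,
    LaserRig,
    PoseEstimate,
)


@dataclass(frozen=True)
class SceneReport:
    camera: CameraIntrinsics
    rig: LaserRig
    measurements: ImageMeasurements
    pose: PoseEstimate
    ground: GroundEstimate
    pixel_error_px: float
    slope_deg: Optional[float] = None
    true_tilt_deg: Optional[float] = None

    def to_dict(self) -> dict:
        from . import __version__

        cam, rig, meas = self.camera, self.rig, self.measurements
        data = {
            "tool": {"name": "laserline", "version": __version__},
            "inputs": {
                "camera": {
                    "alpha_h_deg": cam.alpha_h_deg,
                    "alpha_v_deg": cam.alpha_v_deg,
                    "image_width_px": cam.width_px,
                    "image_height_px": cam.height_px,
                },
                "rig": {
                    "laser_separation_cm": rig.separation_cm,
                    "laser_separation_sigma_cm": rig.separation_sigma_cm,
                },
                "measurements_px": {
                    "n_prime": meas.n_prime,
                    "n_dprime": meas.n_dprime,
                    "n0": meas.n0,
                    "n1": meas.n1,
                    "n2": meas.n2,
                    "m0": meas.m0,
                    "m": meas.m,
                },
                "pixel_error_px": self.pixel_error_px,
            },
            "pose": {
                "tilt_deg": self.pose.tilt_deg,
                "pan_deg": self.pose.pan_deg,
                "cos_tilt": self.pose.cos_tilt,
                "cos_pan": self.pose.cos_pan,
                "vanishing_point_offset_px": {
                    "right_of_center": self.pose.vp_u,
                    "above_center": self.pose.vp_v,
                },
            },
            "ground": {
                "length_cm": self.ground.length_cm,
                "area_cm2": self.ground.area_cm2,
                "height_cm": self.ground.height_cm,
                "delta_length_cm": self.ground.delta_length_cm,
                "delta_area_cm2": self.ground.delta_area_cm2,
                "delta_height_cm": self.ground.delta_height_cm,
                "cot_theta1": self.ground.cot_theta1,
                "cot_theta2": self.ground.cot_theta2,
            },
        }
        if self.true_tilt_deg is not None:
            data["slope"] = {
                "true_tilt_deg": self.true_tilt_deg,
                "seabed_slope_deg": self.slope_deg,
            }
        return data

    def to_flat_dict(self) -> dict:
        """One-level mapping for CSV output."""
        nested = self.to_dict()
        flat: dict = {}

        def _walk(prefix: str, obj: dict) -> None:
            for key, value in obj.items():
                name = f"{prefix}{key}" if not prefix else f"{prefix}.{key}"
                if isinstance(value, dict):
                    _walk(name, value)
                else:
                    flat[name] = value

        _walk("", nested)
        return flat


def measure(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pixel_error_px: float = 1.0,
    true_tilt_deg: Optional[float] = None,
) -> SceneReport:
    """Full estimate for one measurement set."""
    pose = geometry.estimate_pose(meas, cam)
    length = geometry.ground_length(meas, cam, rig, pose)
    area = length * rig.separation_cm
    cot1, cot2 = geometry.perspective_cotangents(meas, cam)
    height = geometry.camera_height(meas, cam, rig, pose)
    rel = uncertainty.relative_uncertainties(meas, cam, rig, pose, pixel_error_px)
    ground = GroundEstimate(
        length_cm=length,
        area_cm2=area,
        height_cm=height,
        delta_length_cm=rel["length"] * length,
        delta_area_cm2=rel["area"] * area,
        delta_height_cm=rel["height"] * height,
        cot_theta1=cot1,
        cot_theta2=cot2,
    )
    slope_deg = None
    if true_tilt_deg is not None:
        slope_deg = math.degrees(
            geometry.seabed_slope(pose.tilt_rad, math.radians(true_tilt_deg))
        )
    return SceneReport(
        camera=cam,
        rig=rig,
        measurements=meas,
        pose=pose,
        ground=ground,
        pixel_error_px=pixel_error_px,
        slope_deg=slope_deg,
        true_tilt_deg=true_tilt_deg,
    )


def measure_annotation(
    ann: AnnotationSet,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pixel_error_px: float = 1.0,
    true_tilt_deg: Optional[float] = None,
) -> SceneReport:
    """Estimate from an annotation set.

    Parallel annotated lines (vanishing point at infinity) mean a
    horizontal, laser-aligned camera; the zero-pose closed forms are
    then used directly.
    """
    from .annotation import measurements_from_annotation

    try:
        meas = measurements_from_annotation(ann)
    except VanishingPointAtInfinity:
        return _measure_zero_pose(ann, cam, rig, pixel_error_px, true_tilt_deg)
    return measure(meas, cam, rig, pixel_error_px, true_tilt_deg)


def _measure_zero_pose(
    ann: AnnotationSet,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pixel_error_px: float,
    true_tilt_deg: Optional[float],
) -> SceneReport:
    """Simple-case estimate for parallel annotated lines."""
    from .models import IDENTITY_POSE

    n_prime = ann.line_right.u_at(ann.near_row_v) - ann.line_left.u_at(ann.near_row_v)
    n_dprime = ann.line_right.u_at(ann.far_row_v) - ann.line_left.u_at(ann.far_row_v)
    length = geometry.ground_length_simple(n_prime, n_dprime, cam, rig)
    area = length * rig.separation_cm
    z_a = (cam.height_px / 2.0 - ann.near_row_v) * cam.vertical_px_scale
    height = geometry.camera_height_simple(z_a, n_prime, rig)
    # slopes of parallel lines still give the cotangent sum
    scale = cam.height_px * cam.tan_half_h / (cam.width_px * cam.tan_half_v)
    cot1 = abs(ann.line_left.slope_du_dv) * scale
    cot2 = abs(ann.line_right.slope_du_dv) * scale
    sep = n_prime - n_dprime
    row_term = (
        (n_dprime / n_prime + n_prime / n_dprime) / sep * pixel_error_px
        if sep > 0
        else 0.0
    )
    dl_over_l = rig.separation_sigma_cm / rig.separation_cm
    rel_length = row_term + dl_over_l
    rel_area = row_term + 2.0 * dl_over_l
    rel_height = pixel_error_px * (1.0 / ann.near_row_v + 2.0 / n_prime) + dl_over_l
    meas_echo = ImageMeasurements(
        n_prime=n_prime,
        n_dprime=n_dprime,
        n0=ann.line_left.u_at(ann.near_row_v),
        n1=n_prime / 2.0,
        n2=n_prime / 2.0,
        m0=cam.height_px - ann.near_row_v,
        m=ann.near_row_v,
    )
    ground = GroundEstimate(
        length_cm=length,
        area_cm2=area,
        height_cm=height,
        delta_length_cm=rel_length * length,
        delta_area_cm2=rel_area * area,
        delta_height_cm=rel_height * height,
        cot_theta1=cot1,
        cot_theta2=cot2,
    )
    slope_deg = None
    if true_tilt_deg is not None:
        slope_deg = -true_tilt_deg
    return SceneReport(
        camera=cam,
        rig=rig,
        measurements=meas_echo,
        pose=IDENTITY_POSE,
        ground=ground,
        pixel_error_px=pixel_error_px,
        slope_deg=slope_deg,
        true_tilt_deg=true_tilt_deg,
    )
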