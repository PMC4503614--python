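"""Closed-form estimators for pose, ground length, area and camera height.

All estimators consume the seven pixel quantities of
:class:`~laserline.models.ImageMeasurements` together with the camera
angles of view and the laser separation.  They are exact inverses of
the pinhole projection of the two-laser rig (see ``laserline.forward``):

* ``tan λ`` is read off the height of the laser-line vanishing point
  above the image center, ``tan γ`` off its horizontal offset;
* the ground separation ``L`` of the two reference rows follows from
  the inverse-separation law — the reciprocal of the line separation
  in pixels grows linearly with ground distance;
* the camera height follows from the image slopes of the two lines
  (the "perspective" cotangents).

``L`` is the separation of the two row ground-traces measured
perpendicular to the traces; under a pan γ the traces make an angle γ
with the lateral axis, and the laser-delimited ground figure between
them has area exactly ``S = L·l``.
"""

from __future__ import annotations

import math
from typing import Optional

from .exceptions import DegenerateGeometryError
from .models import (
    CameraIntrinsics,
    GridOverlay,
    ImageMeasurements,
    LaserRig,
    PoseEstimate,
    Segment,
)

#: Below this image separation of the reference rows (pixels) the
#: relative uncertainty of the length estimate diverges; estimation is
#: refused (an exactly coincident pair of rows returns the limit L = 0).
MIN_ROW_SEPARATION_PX = 0.5


def tilt_from_measurements(
    meas: ImageMeasurements, cam: CameraIntrinsics
) -> tuple[float, float]:
    """Camera tilt from the vanishing-point height.

    Returns ``(cos_tilt, tilt_rad)`` with
    ``tan λ = [m0/M − 1/2 + (n′/(n1+n2))·(m/M)] · 2 tan(α_V/2)``.
    """
    total = meas.n1 + meas.n2
    if total <= 0:
        raise DegenerateGeometryError("vanishing point undefined (n1 + n2 <= 0)")
    big_m = cam.height_px
    bracket = meas.m0 / big_m - 0.5 + (meas.n_prime / total) * (meas.m / big_m)
    tan_tilt = bracket * 2.0 * cam.tan_half_v
    cos_tilt = 1.0 / math.sqrt(1.0 + tan_tilt * tan_tilt)
    return cos_tilt, math.atan(tan_tilt)


def pan_from_measurements(
    meas: ImageMeasurements, cam: CameraIntrinsics, cos_tilt: float
) -> tuple[float, float]:
    """Camera pan from the vanishing-point horizontal offset.

    Returns ``(cos_pan, pan_rad)`` with
    ``tan γ = [1/2 − n0/N − (n1/(n1+n2))·(n′/N)] · 2 tan(α_H/2) · cos λ``
    (signed: positive pan puts the vanishing point left of center).
    """
    total = meas.n1 + meas.n2
    if total <= 0:
        raise DegenerateGeometryError("vanishing point undefined (n1 + n2 <= 0)")
    big_n = cam.width_px
    bracket = 0.5 - meas.n0 / big_n - (meas.n1 / total) * (meas.n_prime / big_n)
    tan_pan = bracket * 2.0 * cam.tan_half_h * cos_tilt
    cos_pan = 1.0 / math.sqrt(1.0 + tan_pan * tan_pan)
    return cos_pan, math.atan(tan_pan)


def vanishing_point(
    tilt_rad: float, pan_rad: float, cam: CameraIntrinsics
) -> tuple[float, float]:
    """Vanishing-point offsets from the image center, pixels.

    Vertical offset (positive up) ``= (M/2)·tan λ / tan(α_V/2)``;
    horizontal offset (positive right) ``= −(N/2)·tan γ / (tan(α_H/2)·cos λ)``.
    A horizontal, laser-aligned camera gives ``(0, 0)``.
    """
    vp_v = (cam.height_px / 2.0) * math.tan(tilt_rad) / cam.tan_half_v
    vp_u = (
        -(cam.width_px / 2.0)
        * math.tan(pan_rad)
        / (cam.tan_half_h * math.cos(tilt_rad))
    )
    return vp_u, vp_v


def estimate_pose(meas: ImageMeasurements, cam: CameraIntrinsics) -> PoseEstimate:
    """Full pose estimate (tilt, pan, vanishing point) from one image."""
    cos_tilt, tilt = tilt_from_measurements(meas, cam)
    cos_pan, pan = pan_from_measurements(meas, cam, cos_tilt)
    vp_u, vp_v = vanishing_point(tilt, pan, cam)
    return PoseEstimate(
        cos_tilt=cos_tilt,
        cos_pan=cos_pan,
        tilt_rad=tilt,
        pan_rad=pan,
        vp_u=vp_u,
        vp_v=vp_v,
    )


def _require_row_separation(n_prime: float, n_dprime: float) -> None:
    if n_dprime > n_prime:
        raise DegenerateGeometryError(
            "far row must be narrower than near row "
            f"(n_prime={n_prime}, n_dprime={n_dprime})"
        )
    if 0.0 < n_prime - n_dprime < MIN_ROW_SEPARATION_PX:
        raise DegenerateGeometryError(
            "reference rows closer than half a pixel; length uncertainty diverges"
        )


def ground_length(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pose: Optional[PoseEstimate] = None,
) -> float:
    """Ground separation ``L`` (cm) of the two reference rows.

    ``L = (n′/n″ − 1) · (N/n′) · l / (2 tan(α_H/2) · cos λ · cos γ)``,
    the perpendicular distance between the ground traces of the rows.
    """
    _require_row_separation(meas.n_prime, meas.n_dprime)
    if meas.n_prime == meas.n_dprime:
        return 0.0
    if pose is None:
        pose = estimate_pose(meas, cam)
    return (
        (meas.n_prime / meas.n_dprime - 1.0)
        * (cam.width_px / meas.n_prime)
        * rig.separation_cm
        / (2.0 * cam.tan_half_h * pose.cos_tilt * pose.cos_pan)
    )


def ground_area(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pose: Optional[PoseEstimate] = None,
) -> float:
    """Ground area ``S = L × l`` (cm²) of the laser-delimited strip."""
    return ground_length(meas, cam, rig, pose) * rig.separation_cm


def perspective_cotangents(
    meas: ImageMeasurements, cam: CameraIntrinsics
) -> tuple[float, float]:
    """Cotangents of the perspective angles of the two laser lines.

    ``cot θᵢ = (nᵢ/N) · (M/m) · tan(α_H/2) / tan(α_V/2)`` — the image
    slope of each line converted to the physically scaled image plane.
    A vertical line (in the physical image) has ``cot θ = 0``.
    """
    if meas.m <= 0:
        raise DegenerateGeometryError("m must be positive")
    scale = (
        (cam.height_px / meas.m) * cam.tan_half_h / (cam.width_px * cam.tan_half_v)
    )
    return meas.n1 * scale, meas.n2 * scale


def camera_height(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pose: Optional[PoseEstimate] = None,
) -> float:
    """Perpendicular camera height above the seabed (cm).

    ``h = (cos λ / cos γ) · l / (cot θ₁ + cot θ₂)``.
    """
    cot1, cot2 = perspective_cotangents(meas, cam)
    if cot1 + cot2 <= 0:
        raise DegenerateGeometryError(
            "laser lines parallel in image; height undefined"
        )
    if pose is None:
        pose = estimate_pose(meas, cam)
    return (pose.cos_tilt / pose.cos_pan) * rig.separation_cm / (cot1 + cot2)


def ground_length_simple(
    n_prime: float, n_dprime: float, cam: CameraIntrinsics, rig: LaserRig
) -> float:
    """Row ground separation for a horizontal, laser-aligned camera:
    ``L = (n′/n″ − 1) · (N/n′) · l / (2 tan(α_H/2))``."""
    if n_dprime <= 0:
        raise DegenerateGeometryError("n_dprime must be positive")
    _require_row_separation(n_prime, n_dprime)
    if n_prime == n_dprime:
        return 0.0
    return (
        (n_prime / n_dprime - 1.0)
        * (cam.width_px / n_prime)
        * rig.separation_cm
        / (2.0 * cam.tan_half_h)
    )


def ground_area_simple(
    n_prime: float, n_dprime: float, cam: CameraIntrinsics, rig: LaserRig
) -> float:
    """Area for a horizontal, laser-aligned camera: ``S = L_simple × l``."""
    return ground_length_simple(n_prime, n_dprime, cam, rig) * rig.separation_cm


def camera_height_simple(z_a_px: float, l_prime_px: float, rig: LaserRig) -> float:
    """Camera height for a horizontal, laser-aligned camera.

    ``z_a_px`` is the signed vertical offset of the near reference row
    below the image center, already converted to the horizontal pixel
    scale (multiply raw vertical pixels by
    :attr:`CameraIntrinsics.vertical_px_scale`); it is negative for a
    row below the center.  ``l_prime_px`` is the laser-line separation
    at that row.  ``h = (−z_A′ / l′) · l``.
    """
    if l_prime_px <= 0:
        raise DegenerateGeometryError("l_prime_px must be positive")
    return (-z_a_px / l_prime_px) * rig.separation_cm


def seabed_slope(apparent_tilt_rad: float, true_tilt_rad: float) -> float:
    """Seabed slope ``α = λ − λ0`` (radians).

    ``λ`` is the image-derived apparent tilt; ``λ0`` the true camera
    tilt from an attitude sensor.  A positive slope rises away from
    the camera.
    """
    return apparent_tilt_rad - true_tilt_rad


def ground_grid_overlay(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    lateral_spacing_cm: float,
    axial_spacing_cm: float,
    pose: Optional[PoseEstimate] = None,
    max_lateral: int = 100,
    max_axial: int = 100,
) -> GridOverlay:
    """Equal-ground-spacing grid in image coordinates.

    Lateral members are images of ground lines parallel to the lasers
    at offsets ``k·lateral_spacing_cm`` from the left laser line
    (``k = 0`` is the left line itself; ``lateral_spacing_cm = l``
    makes both laser lines grid members).  They all pass through the
    vanishing point, with image slope linear in the ground offset.

    Axial members are image rows whose consecutive ground separations
    (by the inverse of the length equation) all equal
    ``axial_spacing_cm``, starting from the near reference row and
    marching away from the camera; rows closer than the far limit of
    the raster or converging onto the vanishing point are dropped.
    """
    if lateral_spacing_cm <= 0 or axial_spacing_cm <= 0:
        raise ValueError("grid spacings must be positive")
    if pose is None:
        pose = estimate_pose(meas, cam)
    big_n, big_m = cam.width_px, cam.height_px
    u_v, v_v = pose.vanishing_point_raster(cam)

    total = meas.n1 + meas.n2
    slope_left = -meas.n1 / meas.m  # du per downward pixel
    slope_right = meas.n2 / meas.m
    dslope = (slope_right - slope_left) / rig.separation_cm

    lateral: list[Segment] = []
    v_bottom = float(big_m)
    for k in range(-max_lateral, max_lateral + 1):
        s = slope_left + k * lateral_spacing_cm * dslope
        u_bottom = u_v + s * (v_bottom - v_v)
        if not -0.5 * big_n <= u_bottom <= 1.5 * big_n:
            continue
        lateral.append(Segment(u1=u_v, v1=v_v, u2=u_bottom, v2=v_bottom))

    # inverse separation grows linearly with perpendicular ground distance
    v_near = big_m - meas.m0
    n_near = (v_near - v_v) * total / meas.m
    if n_near <= 0:
        raise DegenerateGeometryError("near reference row lies above the vanishing point")
    step = (
        axial_spacing_cm
        * 2.0
        * cam.tan_half_h
        * pose.cos_tilt
        * pose.cos_pan
        / (big_n * rig.separation_cm)
    )
    axial: list[Segment] = []
    inv_n = 1.0 / n_near
    for _ in range(max_axial):
        n_k = 1.0 / inv_n
        v_k = v_v + n_k * meas.m / total
        if v_k <= max(v_v, 0.0) or v_k > big_m:
            break
        axial.append(
            Segment(
                u1=u_v + slope_left * (v_k - v_v),
                v1=v_k,
                u2=u_v + slope_right * (v_k - v_v),
                v2=v_k,
            )
        )
        inv_n += step
    return GridOverlay(lateral=tuple(lateral), axial=tuple(axial))
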