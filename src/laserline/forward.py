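"""Exact pinhole forward projection of the camera + two-laser rig.

The scene lives in a ground frame attached to the seabed surface:
lateral axis ``x`` rightward, axial axis ``y`` along the laser lines
away from the camera, normal axis ``z`` up; the camera sits at the
origin at height ``h`` (perpendicular distance above the plane).  The
world-to-camera rotation is pan about the plane normal first, then
tilt about the camera's horizontal axis:

    p_cam = R_x(λ) · R_z(γ) · p_ground

with camera axes x right, y along the optical axis, z up.  Raster
conversion uses the horizontal scale ``N/(2 tan(α_H/2))`` and vertical
scale ``M/(2 tan(α_V/2))`` per unit tangent.  A seabed slope simply
adds to the tilt (the estimators see the apparent tilt λ0 + α).

This module is the test oracle of the package: with unquantized
synthesized measurements every closed-form estimator recovers the
scene exactly, and the ground truths it reports carry the exact
geometric meaning of the estimated quantities (the row ground length
is the perpendicular separation of the two row traces; the area is
that length times the laser separation).
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np

from . import annotation as _annotation
from .exceptions import DegenerateGeometryError
from .models import AnnotationSet, ForwardScene, ImageLine, ImageMeasurements


def rotation_matrix(scene: ForwardScene) -> np.ndarray:
    """Ground-to-camera rotation (pan about the plane normal, then tilt)."""
    lam = scene.apparent_tilt_rad
    gam = scene.pan_rad
    cl, sl = np.cos(lam), np.sin(lam)
    cg, sg = np.cos(gam), np.sin(gam)
    r_pan = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    r_tilt = np.array([[1.0, 0.0, 0.0], [0.0, cl, -sl], [0.0, sl, cl]])
    return r_tilt @ r_pan


def project_point(
    scene: ForwardScene, x_cm: float, y_cm: float
) -> tuple[float, float]:
    """Project the ground point ``(x, y)`` to raster coordinates.

    Rejects points that are behind the camera after rotation.
    """
    cam = scene.camera
    p = rotation_matrix(scene) @ np.array([x_cm, y_cm, -scene.height_cm])
    if p[1] <= 0:
        raise DegenerateGeometryError(
            f"ground point ({x_cm}, {y_cm}) lies behind the camera"
        )
    u = cam.width_px / 2.0 + (cam.width_px / 2.0) * (p[0] / p[1]) / cam.tan_half_h
    v = cam.height_px / 2.0 - (cam.height_px / 2.0) * (p[2] / p[1]) / cam.tan_half_v
    return float(u), float(v)


def ground_point_at_row(scene: ForwardScene, x_cm: float, v_px: float) -> float:
    """Axial coordinate ``y`` of the point of the ground line
    ``x = x_cm`` that projects onto image row ``v_px`` (closed form)."""
    cam = scene.camera
    lam, gam, h = scene.apparent_tilt_rad, scene.pan_rad, scene.height_cm
    cl, sl = np.cos(lam), np.sin(lam)
    cg, sg = np.cos(gam), np.sin(gam)
    zeta = (cam.height_px / 2.0 - v_px) * 2.0 * cam.tan_half_v / cam.height_px
    num_a = sl * x_cm * sg - cl * h
    num_b = sl * cg
    den_c = cl * x_cm * sg + sl * h
    den_d = cl * cg
    denom = num_b - zeta * den_d
    if abs(denom) < 1e-300:
        raise DegenerateGeometryError("row maps to the vanishing line")
    y = (zeta * den_c - num_a) / denom
    if y <= 0:
        raise DegenerateGeometryError(
            f"row v={v_px} does not intersect the visible ground"
        )
    return float(y)


def ground_from_pixel(
    scene: ForwardScene, u_px: float, v_px: float
) -> tuple[float, float]:
    """Back-project a raster point onto the ground plane."""
    cam = scene.camera
    xi = (u_px - cam.width_px / 2.0) * 2.0 * cam.tan_half_h / cam.width_px
    zeta = (cam.height_px / 2.0 - v_px) * 2.0 * cam.tan_half_v / cam.height_px
    direction = rotation_matrix(scene).T @ np.array([xi, 1.0, zeta])
    if direction[2] >= 0:
        raise DegenerateGeometryError("pixel ray does not hit the ground")
    t = -scene.height_cm / direction[2]
    return float(direction[0] * t), float(direction[1] * t)


def vanishing_point_raster(scene: ForwardScene) -> tuple[float, float]:
    """Raster coordinates of the laser-line vanishing point."""
    cam = scene.camera
    lam, gam = scene.apparent_tilt_rad, scene.pan_rad
    u = cam.width_px / 2.0 - (cam.width_px / 2.0) * np.tan(gam) / (
        cam.tan_half_h * np.cos(lam)
    )
    v = cam.height_px / 2.0 - (cam.height_px / 2.0) * np.tan(lam) / cam.tan_half_v
    return float(u), float(v)


def render_laser_lines(
    scene: ForwardScene, y_near_cm: float, y_far_cm: float
) -> tuple[ImageLine, ImageLine]:
    """Project the two laser lines between the given axial ground
    distances; returns (left, right) image lines.  With zero roll the
    projections are exactly straight, so the segments extrapolate
    losslessly to any image row."""
    if not 0 < y_near_cm < y_far_cm:
        raise ValueError("need 0 < y_near_cm < y_far_cm")
    lines = []
    for x in (-scene.left_offset_cm, scene.right_offset_cm):
        u1, v1 = project_point(scene, x, y_near_cm)
        u2, v2 = project_point(scene, x, y_far_cm)
        lines.append(ImageLine(u1=u1, v1=v1, u2=u2, v2=v2))
    return lines[0], lines[1]


def row_trace_length(
    scene: ForwardScene, near_row_v: float, far_row_v: float
) -> float:
    """Exact perpendicular ground distance between the traces of two
    image rows.  Each row back-projects to a ground line making angle
    −γ with the lateral axis; the axial offset between the traces is
    constant, so the perpendicular distance is that offset times cos γ.
    """
    y_near = ground_point_at_row(scene, 0.0, near_row_v)
    y_far = ground_point_at_row(scene, 0.0, far_row_v)
    return (y_far - y_near) * float(np.cos(scene.pan_rad))


def annotation_for_scene(
    scene: ForwardScene, near_row_v: float, far_row_v: float
) -> AnnotationSet:
    """Exact annotation of the rendered laser lines at two rows."""
    v_v = vanishing_point_raster(scene)[1]
    if not v_v < far_row_v < near_row_v:
        raise ValueError(
            "reference rows must lie below the vanishing point "
            f"(v_V={v_v:.1f}, far={far_row_v}, near={near_row_v})"
        )
    y_lo = min(
        ground_point_at_row(scene, -scene.left_offset_cm, near_row_v),
        ground_point_at_row(scene, scene.right_offset_cm, near_row_v),
    )
    left, right = render_laser_lines(scene, 0.5 * y_lo, 4.0 * y_lo + scene.height_cm)
    if left.u_at(near_row_v) > right.u_at(near_row_v):
        left, right = right, left
    return AnnotationSet(
        line_left=left,
        line_right=right,
        near_row_v=near_row_v,
        far_row_v=far_row_v,
        width_px=scene.camera.width_px,
        height_px=scene.camera.height_px,
    )


def ground_truth(
    scene: ForwardScene, near_row_v: float, far_row_v: float
) -> dict[str, float]:
    """Analytic ground truth for the quantities the estimators report."""
    length = row_trace_length(scene, near_row_v, far_row_v)
    return {
        "length_cm": length,
        "area_cm2": length * scene.separation_cm,
        "height_cm": scene.height_cm,
        "tilt_deg": float(np.degrees(scene.apparent_tilt_rad)),
        "pan_deg": float(np.degrees(scene.pan_rad)),
    }


def synthesize_measurements(
    scene: ForwardScene,
    near_row_v: float,
    far_row_v: float,
    quantize: bool = False,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> tuple[ImageMeasurements, dict[str, float]]:
    """Exact (or integer-quantized) pixel measurements plus ground truth.

    Quantization rounds each of the seven quantities to the nearest
    integer pixel, emulating manual annotation at whole-pixel
    precision; exact-half cases are dithered with ``rng``.
    """
    ann = annotation_for_scene(scene, near_row_v, far_row_v)
    meas = _annotation.measurements_from_annotation(ann)
    if quantize:
        gen = (
            rng
            if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )

        def _round(value: float) -> float:
            frac = value - np.floor(value)
            if abs(frac - 0.5) < 1e-9:
                return float(np.floor(value) + gen.integers(0, 2))
            return float(np.round(value))

        meas = ImageMeasurements(
            n_prime=_round(meas.n_prime),
            n_dprime=_round(meas.n_dprime),
            n0=_round(meas.n0),
            n1=_round(meas.n1),
            n2=_round(meas.n2),
            m0=_round(meas.m0),
            m=_round(meas.m),
        )
    return meas, ground_truth(scene, near_row_v, far_row_v)


def render_synthetic_image(
    scene: ForwardScene,
    path: Optional[Union[str, os.PathLike]] = None,
    line_width_px: float = 2.5,
    background: str = "flat",
    seed: int = 0,
) -> np.ndarray:
    """Render an RGB still with two anti-aliased green laser lines.

    ``background`` is ``"flat"``, ``"gradient"`` (vertical luminance
    ramp) or ``"speckle"`` (seeded Gaussian sensor noise).  Returns the
    HxWx3 uint8 array; also writes a PNG when ``path`` is given (the
    file is byte-identical for identical scene, parameters and seed).
    """
    cam = scene.camera
    n_cols, n_rows = cam.width_px, cam.height_px
    img = np.zeros((n_rows, n_cols, 3), dtype=np.float64)

    if background == "flat":
        img[:] = (18.0, 26.0, 34.0)
    elif background == "gradient":
        ramp = np.linspace(10.0, 60.0, n_rows)[:, None, None]
        img[:] = ramp + np.array([8.0, 16.0, 24.0])
    elif background == "speckle":
        rng = np.random.default_rng(seed)
        img[:] = (18.0, 26.0, 34.0)
        img += rng.normal(0.0, 12.0, size=img.shape)
    else:
        raise ValueError(f"unknown background {background!r}")

    v_v = vanishing_point_raster(scene)[1]
    sigma = line_width_px / 2.0
    half_window = max(1, int(np.ceil(4.0 * sigma)))
    rows = np.arange(n_rows)
    v_centers = rows + 0.5
    visible = v_centers > v_v + 2.0
    y_ref = scene.height_cm  # any positive axial anchor for the line equation
    left, right = render_laser_lines(scene, 0.5 * y_ref, 5.0 * y_ref)
    for line in (left, right):
        centers = line.u1 + line.slope_du_dv * (v_centers - line.v1)
        for j in rows[visible]:
            c = centers[j]
            lo = int(np.floor(c - half_window))
            hi = int(np.ceil(c + half_window)) + 1
            lo_c, hi_c = max(lo, 0), min(hi, n_cols)
            if lo_c >= hi_c:
                continue
            cols = np.arange(lo_c, hi_c)
            profile = np.exp(-0.5 * ((cols + 0.5 - c) / sigma) ** 2)
            img[j, lo_c:hi_c, 0] += 25.0 * profile
            img[j, lo_c:hi_c, 1] += 215.0 * profile
            img[j, lo_c:hi_c, 2] += 35.0 * profile

    out = np.clip(img, 0.0, 255.0).astype(np.uint8)
    if path is not None:
        from PIL import Image

        Image.fromarray(out, mode="RGB").save(os.fspath(path), format="PNG")
    return out
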