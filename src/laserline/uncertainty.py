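"""Maximal first-order uncertainty propagation.

Every uncertainty here is a *maximal* error — the absolute-value sum of
the first-order contributions of each input error — not a statistical
quadrature.  The pixel error of each measured quantity defaults to one
pixel (the natural floor of manual annotation); the laser-separation
error comes from the rig calibration.

The closed forms below are the partial-derivative sums of the length,
area and height estimators with respect to (n′, n″, cos γ, cos λ, l).
A finite-difference cross-check of the same absolute-sum rule lives in
the test suite.
"""

from __future__ import annotations

import math
from typing import Optional

from .geometry import estimate_pose
from .models import CameraIntrinsics, ImageMeasurements, LaserRig, PoseEstimate


def rel_unc_cos_tilt(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    cos_tilt: float,
    pixel_error_px: float = 1.0,
) -> float:
    """Relative maximal uncertainty of cos λ.

    ``Δcosλ/cosλ = |m0/M − 1/2 + (n′/(n1+n2))(m/M)| · [2 tan(α_V/2)·cosλ]²
    · [(1 + n′/(n1+n2))/M + (1 + 2n′/(n1+n2))/(n1+n2)]``
    (for a one-pixel error; scales linearly with the pixel error).
    """
    total = meas.n1 + meas.n2
    ratio = meas.n_prime / total
    big_m = cam.height_px
    bracket = abs(meas.m0 / big_m - 0.5 + ratio * meas.m / big_m)
    factor = (2.0 * cam.tan_half_v * cos_tilt) ** 2
    resolution = (1.0 + ratio) / big_m + (1.0 + 2.0 * ratio) / total
    return bracket * factor * resolution * pixel_error_px


def rel_unc_cos_pan(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    cos_tilt: float,
    cos_pan: float,
    ruc_cos_tilt: float,
    pixel_error_px: float = 1.0,
) -> float:
    """Relative maximal uncertainty of cos γ.

    ``Δcosγ/cosγ = [2 tan(α_H/2)·cosλ·cosγ]² · |1/2 − n0/N − (n1/(n1+n2))(n′/N)|
    · {[1 + (1 + 2n1/(n1+n2))·n′/(n1+n2)]/N
       + |1/2 − n0/N − (n1/(n1+n2))(n′/N)| · Δcosλ/cosλ}``.
    """
    total = meas.n1 + meas.n2
    big_n = cam.width_px
    bracket = abs(0.5 - meas.n0 / big_n - (meas.n1 / total) * (meas.n_prime / big_n))
    factor = (2.0 * cam.tan_half_h * cos_tilt * cos_pan) ** 2
    resolution = (
        1.0 + (1.0 + 2.0 * meas.n1 / total) * meas.n_prime / total
    ) / big_n
    return factor * bracket * (resolution * pixel_error_px + bracket * ruc_cos_tilt)


def _row_term(meas: ImageMeasurements, pixel_error_px: float) -> float:
    """Pixel-resolution term of the length/area uncertainty:
    ``(n″/n′ + n′/n″)/(n′ − n″)`` per pixel of measurement error."""
    sep = meas.n_prime - meas.n_dprime
    if sep <= 0:
        return math.inf
    return (
        (meas.n_dprime / meas.n_prime + meas.n_prime / meas.n_dprime)
        / sep
        * pixel_error_px
    )


def rel_unc_length(
    meas: ImageMeasurements,
    rig: LaserRig,
    ruc_cos_pan: float,
    ruc_cos_tilt: float,
    pixel_error_px: float = 1.0,
) -> float:
    """``ΔL/L = (n″/n′ + n′/n″)/(n′ − n″) + Δcosγ/cosγ + Δcosλ/cosλ + Δl/l``."""
    return (
        _row_term(meas, pixel_error_px)
        + ruc_cos_pan
        + ruc_cos_tilt
        + rig.separation_sigma_cm / rig.separation_cm
    )


def rel_unc_area(
    meas: ImageMeasurements,
    rig: LaserRig,
    ruc_cos_pan: float,
    ruc_cos_tilt: float,
    pixel_error_px: float = 1.0,
) -> float:
    """``ΔS/S = ΔL/L + Δl/l`` (the laser separation enters the area twice)."""
    return (
        _row_term(meas, pixel_error_px)
        + ruc_cos_pan
        + ruc_cos_tilt
        + 2.0 * rig.separation_sigma_cm / rig.separation_cm
    )


def rel_unc_height(
    meas: ImageMeasurements,
    rig: LaserRig,
    ruc_cos_pan: float,
    ruc_cos_tilt: float,
    pixel_error_px: float = 1.0,
) -> float:
    """``Δh/h = 1/m + 2/(n1+n2) + Δcosγ/cosγ + Δcosλ/cosλ + Δl/l``."""
    return (
        (1.0 / meas.m + 2.0 / (meas.n1 + meas.n2)) * pixel_error_px
        + ruc_cos_pan
        + ruc_cos_tilt
        + rig.separation_sigma_cm / rig.separation_cm
    )


def relative_uncertainties(
    meas: ImageMeasurements,
    cam: CameraIntrinsics,
    rig: LaserRig,
    pose: Optional[PoseEstimate] = None,
    pixel_error_px: float = 1.0,
) -> dict[str, float]:
    """All relative maximal uncertainties for one measurement set.

    Returns a dict with keys ``cos_tilt``, ``cos_pan``, ``length``,
    ``area``, ``height`` (dimensionless relative values).
    """
    if pose is None:
        pose = estimate_pose(meas, cam)
    ruc_tilt = rel_unc_cos_tilt(meas, cam, pose.cos_tilt, pixel_error_px)
    ruc_pan = rel_unc_cos_pan(
        meas, cam, pose.cos_tilt, pose.cos_pan, ruc_tilt, pixel_error_px
    )
    return {
        "cos_tilt": ruc_tilt,
        "cos_pan": ruc_pan,
        "length": rel_unc_length(meas, rig, ruc_pan, ruc_tilt, pixel_error_px),
        "area": rel_unc_area(meas, rig, ruc_pan, ruc_tilt, pixel_error_px),
        "height": rel_unc_height(meas, rig, ruc_pan, ruc_tilt, pixel_error_px),
    }


def reference_area_uncertainty(
    length_cm: float,
    delta_length_cm: float,
    separation_cm: float,
    delta_separation_cm: float,
) -> float:
    """Maximal uncertainty of a reference area ``S = L × l`` from
    independently known ``L ± ΔL`` and ``l ± Δl``:
    ``ΔS = S · (ΔL/L + Δl/l)``."""
    area = length_cm * separation_cm
    return area * (
        delta_length_cm / length_cm + delta_separation_cm / separation_cm
    )
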