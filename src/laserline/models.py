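"""Domain types: camera, laser rig, pixel measurements, pose, scene.

Conventions (frozen throughout the package):

* Raster coordinates ``(u, v)`` are real-valued, origin at the top-left
  corner of the image, ``u`` rightward in ``[0, N]``, ``v`` downward in
  ``[0, M]``; the optical center is at ``(N/2, M/2)`` and the center of
  pixel ``(row j, col i)`` is ``(i + 0.5, j + 0.5)``.
* The centered image frame has horizontal axis rightward and vertical
  axis UP; vertical offsets reported by the pose estimators are
  positive above the image center.
* Angles cross the public interfaces in degrees and are stored in
  radians; lengths are centimetres, areas cm².
* Downward camera tilt is ``tilt > 0`` and moves the vanishing point up;
  positive pan is a rotation of the camera to the right and moves the
  vanishing point LEFT of center (the world-fixed laser direction
  shifts opposite to the camera's rotation).
* Camera roll is assumed zero everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class CameraIntrinsics:
    """Angles of view and pixel grid of the recording camera.

    The physical sensor width never enters any estimate: it cancels in
    every ratio, so the angles of view and the pixel counts fully
    characterise the image-side scale.

    Parameters
    ----------
    alpha_h_deg, alpha_v_deg:
        Full horizontal / vertical angle of view, degrees, in (0, 180).
    width_px, height_px:
        Image width ``N`` and height ``M`` in pixels.
    """

    alpha_h_deg: float
    alpha_v_deg: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_h_deg < 180.0:
            raise ValueError(f"alpha_h_deg must be in (0, 180), got {self.alpha_h_deg}")
        if not 0.0 < self.alpha_v_deg < 180.0:
            raise ValueError(f"alpha_v_deg must be in (0, 180), got {self.alpha_v_deg}")
        if self.width_px < 2 or self.height_px < 2:
            raise ValueError("image must be at least 2x2 pixels")

    @property
    def tan_half_h(self) -> float:
        """tan(alpha_H / 2) — horizontal tangent per half image width."""
        return math.tan(math.radians(self.alpha_h_deg) / 2.0)

    @property
    def tan_half_v(self) -> float:
        """tan(alpha_V / 2) — vertical tangent per half image height."""
        return math.tan(math.radians(self.alpha_v_deg) / 2.0)

    @property
    def vertical_px_scale(self) -> float:
        """Factor converting vertical pixels to the horizontal pixel
        scale: ``N·tan(alpha_V/2) / (M·tan(alpha_H/2))``."""
        return (self.width_px * self.tan_half_v) / (self.height_px * self.tan_half_h)


@dataclass(frozen=True)
class LaserRig:
    """The two parallel sheet lasers rigidly mounted to the vehicle frame.

    Parameters
    ----------
    separation_cm:
        Ground separation ``l`` of the two laser lines, cm.
    separation_sigma_cm:
        Calibration uncertainty of the separation, cm (maximal, not
        statistical).  0.5 cm is typical of hand-calibrated rigs.
    left_offset_cm, right_offset_cm:
        Optional distances from the optical-axis ground track to the
        left / right laser line; must sum to the separation when given.
    """

    separation_cm: float
    separation_sigma_cm: float = 0.5
    left_offset_cm: Optional[float] = None
    right_offset_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.separation_cm <= 0:
            raise ValueError("laser separation must be positive")
        if self.separation_sigma_cm < 0:
            raise ValueError("separation uncertainty must be >= 0")
        given = (self.left_offset_cm is None, self.right_offset_cm is None)
        if given == (False, False):
            total = self.left_offset_cm + self.right_offset_cm
            if abs(total - self.separation_cm) > 1e-9 * self.separation_cm:
                raise ValueError(
                    "left_offset_cm + right_offset_cm must equal separation_cm "
                    f"({total} != {self.separation_cm})"
                )
        elif given in ((True, False), (False, True)):
            raise ValueError("give both per-side offsets or neither")


@dataclass(frozen=True)
class ImageMeasurements:
    """The seven pixel quantities read off a single still image.

    ``n_prime`` and ``n_dprime`` are the horizontal separations of the
    two projected laser lines at the near and far reference rows.
    ``n0`` is the horizontal raster coordinate of the left line at the
    near row, and ``m0`` the height of the near row above the BOTTOM
    image edge.  ``n1`` and ``n2`` are the horizontal distances from
    the vertical through the vanishing point to the left and right
    lines at any row ``m`` pixels below the vanishing point; only the
    ratios ``n1/m`` and ``n2/m`` (the image slopes of the lines) enter
    any estimate, so the choice of measurement row is free.

    ``n1`` may be negative when a strong pan puts the vanishing-point
    vertical outside the two lines; the sum ``n1 + n2`` must stay
    positive.
    """

    n_prime: float
    n_dprime: float
    n0: float
    n1: float
    n2: float
    m0: float
    m: float

    def __post_init__(self) -> None:
        if self.n_dprime <= 0:
            raise ValueError("n_dprime must be positive")
        if self.n_prime < self.n_dprime:
            raise ValueError(
                "far row must be narrower than near row "
                f"(n_prime={self.n_prime} < n_dprime={self.n_dprime})"
            )
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.n1 + self.n2 <= 0:
            raise ValueError("n1 + n2 must be positive (vanishing point undefined)")
        # n0 (and under strong pan even n1) may be negative: a line's
        # extrapolated raster coordinate can fall outside the image.
        for name in ("n_prime", "n_dprime", "n0", "n1", "n2", "m0", "m"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class MeasurementErrors:
    """Assumed maximal errors of the pixel measurements.

    One pixel per measured quantity is the natural floor for manual
    annotation of an uncompressed still; sub-pixel annotation or
    detection pipelines may justify less.
    """

    pixel_error_px: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_error_px < 0:
            raise ValueError("pixel error must be >= 0")


@dataclass(frozen=True)
class PoseEstimate:
    """Camera orientation relative to the laser direction.

    ``vp_u`` and ``vp_v`` are the vanishing-point offsets from the
    image center, positive rightward / upward, pixels.
    """

    cos_tilt: float
    cos_pan: float
    tilt_rad: float
    pan_rad: float
    vp_u: float
    vp_v: float

    @property
    def tilt_deg(self) -> float:
        return math.degrees(self.tilt_rad)

    @property
    def pan_deg(self) -> float:
        return math.degrees(self.pan_rad)

    def vanishing_point_raster(self, cam: CameraIntrinsics) -> tuple[float, float]:
        """Vanishing point in raster coordinates (may lie outside the image)."""
        return cam.width_px / 2.0 + self.vp_u, cam.height_px / 2.0 - self.vp_v

    def __post_init__(self) -> None:
        if not 0.0 < self.cos_tilt <= 1.0 or not 0.0 < self.cos_pan <= 1.0:
            raise ValueError("pose cosines must be in (0, 1]")


IDENTITY_POSE = PoseEstimate(
    cos_tilt=1.0, cos_pan=1.0, tilt_rad=0.0, pan_rad=0.0, vp_u=0.0, vp_v=0.0
)


@dataclass(frozen=True)
class GroundEstimate:
    """Ground-scale results for one still image.

    ``length_cm`` is the ground separation of the two reference rows,
    measured perpendicular to their ground traces; ``area_cm2`` is
    always ``length_cm × separation_cm``.  The deltas are maximal
    (absolute-sum) first-order uncertainties.
    """

    length_cm: float
    area_cm2: float
    height_cm: float
    delta_length_cm: float
    delta_area_cm2: float
    delta_height_cm: float
    cot_theta1: float
    cot_theta2: float

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise ValueError("length must be >= 0")
        for d in (self.delta_length_cm, self.delta_area_cm2, self.delta_height_cm):
            if d < 0:
                raise ValueError("uncertainties must be >= 0")


@dataclass(frozen=True)
class ImageLine:
    """A straight image line given by two distinct endpoints in raster
    pixel coordinates.  Must not be horizontal (a horizontal projected
    laser line means the camera is horizontal and row separations are
    undefined)."""

    u1: float
    v1: float
    u2: float
    v2: float

    def __post_init__(self) -> None:
        if abs(self.v2 - self.v1) <= 1e-9:
            raise ValueError("line endpoints must differ in v (line is horizontal)")
        if self.u1 == self.u2 and self.v1 == self.v2:
            raise ValueError("line endpoints must be distinct")

    @property
    def slope_du_dv(self) -> float:
        """Horizontal pixels per downward pixel."""
        return (self.u2 - self.u1) / (self.v2 - self.v1)

    def u_at(self, v: float) -> float:
        """Horizontal raster coordinate of the line at row ``v``
        (linear extrapolation beyond the endpoints is exact for a
        projective line)."""
        return self.u1 + self.slope_du_dv * (v - self.v1)


@dataclass(frozen=True)
class AnnotationSet:
    """Two annotated laser-line segments plus two horizontal reference rows."""

    line_left: ImageLine
    line_right: ImageLine
    near_row_v: float
    far_row_v: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.near_row_v <= self.far_row_v:
            raise ValueError(
                "near_row_v must be below far_row_v in the raster "
                f"({self.near_row_v} <= {self.far_row_v})"
            )
        # left/right identity comes from position at the near row, not
        # from the order the lines were supplied in
        if self.line_right.u_at(self.near_row_v) < self.line_left.u_at(
            self.near_row_v
        ):
            left, right = self.line_right, self.line_left
            object.__setattr__(self, "line_left", left)
            object.__setattr__(self, "line_right", right)
        for v in (self.near_row_v, self.far_row_v):
            if self.line_right.u_at(v) <= self.line_left.u_at(v):
                raise ValueError(
                    f"right line must lie right of left line at row v={v}"
                )


@dataclass(frozen=True)
class ForwardScene:
    """Ground-truth scene for the exact pinhole forward model.

    The camera sits at the origin, ``height_cm`` above the ground plane
    (perpendicular distance), pitched down by ``tilt_rad`` and panned by
    ``pan_rad`` relative to the laser direction; the laser lines run
    along the ground axial axis at lateral offsets ``-left_offset_cm``
    and ``+right_offset_cm``.  A non-zero ``ground_slope_rad`` inclines
    the seabed along the laser direction (rising away from the camera),
    which simply adds to the apparent tilt.
    """

    camera: CameraIntrinsics
    height_cm: float
    tilt_rad: float
    pan_rad: float
    left_offset_cm: float
    right_offset_cm: float
    ground_slope_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError("camera height must be positive")
        if not 0.0 <= self.apparent_tilt_rad < math.pi / 2:
            raise ValueError("tilt + slope must be in [0, 90) degrees")
        if not abs(self.pan_rad) < math.pi / 2:
            raise ValueError("|pan| must be < 90 degrees")
        if self.left_offset_cm + self.right_offset_cm <= 0:
            raise ValueError("laser separation must be positive")

    @property
    def separation_cm(self) -> float:
        return self.left_offset_cm + self.right_offset_cm

    @property
    def apparent_tilt_rad(self) -> float:
        """Tilt of the optical axis relative to the (possibly sloping)
        seabed surface — the angle the image-based estimators see."""
        return self.tilt_rad + self.ground_slope_rad

    def rig(self, separation_sigma_cm: float = 0.5) -> LaserRig:
        return LaserRig(
            separation_cm=self.separation_cm,
            separation_sigma_cm=separation_sigma_cm,
            left_offset_cm=self.left_offset_cm,
            right_offset_cm=self.right_offset_cm,
        )


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the green laser-line extractor."""

    green_excess_threshold: float = 0.25
    min_row_support: float = 0.5
    robust_fit_iterations: int = 20
    cluster_gap_px: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 < self.green_excess_threshold < 1.0:
            raise ValueError("green_excess_threshold must be in (0, 1)")
        if not 0.0 < self.min_row_support <= 1.0:
            raise ValueError("min_row_support must be in (0, 1]")
        if self.robust_fit_iterations < 1:
            raise ValueError("robust_fit_iterations must be >= 1")
        if self.cluster_gap_px <= 0:
            raise ValueError("cluster_gap_px must be positive")


@dataclass(frozen=True)
class Segment:
    """An unconstrained drawable image segment (grid members may be
    horizontal, unlike annotated laser lines)."""

    u1: float
    v1: float
    u2: float
    v2: float


@dataclass(frozen=True)
class GridOverlay:
    """Equal-ground-spacing grid drawn in image coordinates: segments
    parallel to the laser lines (lateral) and equal-ground-length row
    segments (axial)."""

    lateral: tuple[Segment, ...] = field(default_factory=tuple)
    axial: tuple[Segment, ...] = field(default_factory=tuple)
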