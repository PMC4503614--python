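"""From annotated laser lines to pixel measurements, plus file I/O.

An :class:`~laserline.models.AnnotationSet` holds the two laser-line
segments (raster endpoints, sub-pixel, unrounded) and two horizontal
reference rows.  The measurement extractor intersects the lines to
construct the vanishing point and reads the seven pixel quantities off
the near reference row — the largest lever arm available, which
minimises the uncertainty of the slope-derived quantities.  Since only
slope ratios enter the estimators, any other measurement row would
give identical estimates (m-invariance).
"""

from __future__ import annotations

import csv
import json
import math
import os
from typing import Union

from .exceptions import AnnotationError, VanishingPointAtInfinity
from .models import AnnotationSet, ImageLine, ImageMeasurements

#: Two image lines whose directions differ by less than this angle
#: (radians) are treated as parallel: the vanishing point is at
#: infinity and the camera is effectively horizontal with zero pan.
PARALLEL_TOLERANCE_RAD = 1e-12


def line_intersection(a: ImageLine, b: ImageLine) -> tuple[float, float]:
    """Intersection of two image lines in raster coordinates.

    The point may lie outside the raster (the vanishing point usually
    does).  Raises :class:`VanishingPointAtInfinity` for parallel
    lines; the caller may then fall back to the zero-pose estimators.
    """
    d1u, d1v = a.u2 - a.u1, a.v2 - a.v1
    d2u, d2v = b.u2 - b.u1, b.v2 - b.v1
    cross = d1u * d2v - d1v * d2u
    norm = math.hypot(d1u, d1v) * math.hypot(d2u, d2v)
    if abs(cross) <= PARALLEL_TOLERANCE_RAD * norm:
        raise VanishingPointAtInfinity(
            "vanishing point at infinity; treat as zero pan/tilt"
        )
    t = ((b.u1 - a.u1) * d2v - (b.v1 - a.v1) * d2u) / cross
    return a.u1 + t * d1u, a.v1 + t * d1v


def measurements_from_annotation(ann: AnnotationSet) -> ImageMeasurements:
    """Extract the seven pixel quantities from an annotation set.

    All values stay real-valued (no rounding).  The left/right identity
    of the lines is taken from their horizontal order at the near row,
    not from the annotation order.
    """
    left, right = ann.line_left, ann.line_right
    if left.u_at(ann.near_row_v) > right.u_at(ann.near_row_v):
        left, right = right, left

    u_left_near = left.u_at(ann.near_row_v)
    u_right_near = right.u_at(ann.near_row_v)
    n_prime = u_right_near - u_left_near
    n_dprime = right.u_at(ann.far_row_v) - left.u_at(ann.far_row_v)
    if n_dprime <= 0:
        raise AnnotationError(
            "laser lines cross between the reference rows; check annotation"
        )
    if n_dprime >= n_prime:
        raise AnnotationError(
            "rows swapped or lines diverge upward "
            f"(near separation {n_prime:.3f} px <= far separation {n_dprime:.3f} px)"
        )

    u_v, v_v = line_intersection(left, right)
    if v_v >= ann.near_row_v:
        raise AnnotationError(
            "lines diverge toward the horizon (vanishing point below the "
            "near reference row); check annotation"
        )

    return ImageMeasurements(
        n_prime=n_prime,
        n_dprime=n_dprime,
        n0=u_left_near,
        n1=u_v - u_left_near,
        n2=u_right_near - u_v,
        m0=ann.height_px - ann.near_row_v,
        m=ann.near_row_v - v_v,
    )


# ---------------------------------------------------------------------------
# file formats

_CSV_FIELDS = (
    "width_px",
    "height_px",
    "left_u1",
    "left_v1",
    "left_u2",
    "left_v2",
    "right_u1",
    "right_v1",
    "right_u2",
    "right_v2",
    "near_row_v",
    "far_row_v",
)


def _ann_to_dict(ann: AnnotationSet) -> dict:
    return {
        "image": {"width_px": ann.width_px, "height_px": ann.height_px},
        "line_left": {
            "u1": ann.line_left.u1,
            "v1": ann.line_left.v1,
            "u2": ann.line_left.u2,
            "v2": ann.line_left.v2,
        },
        "line_right": {
            "u1": ann.line_right.u1,
            "v1": ann.line_right.v1,
            "u2": ann.line_right.u2,
            "v2": ann.line_right.v2,
        },
        "near_row_v": ann.near_row_v,
        "far_row_v": ann.far_row_v,
    }


def _ann_from_dict(data: dict) -> AnnotationSet:
    try:
        image = data["image"]
        lines = {}
        for key in ("line_left", "line_right"):
            spec = data[key]
            lines[key] = ImageLine(
                u1=float(spec["u1"]),
                v1=float(spec["v1"]),
                u2=float(spec["u2"]),
                v2=float(spec["v2"]),
            )
        return AnnotationSet(
            line_left=lines["line_left"],
            line_right=lines["line_right"],
            near_row_v=float(data["near_row_v"]),
            far_row_v=float(data["far_row_v"]),
            width_px=int(image["width_px"]),
            height_px=int(image["height_px"]),
        )
    except KeyError as exc:
        raise AnnotationError(f"annotation file missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"malformed annotation file: {exc}") from exc


def read_annotation(path: Union[str, os.PathLike]) -> AnnotationSet:
    """Read an annotation file (JSON canonical, ``.csv`` flat dialect).

    Extra metadata keys are tolerated; missing or malformed fields
    raise :class:`AnnotationError` naming the offending field.
    """
    path = os.fspath(path)
    if path.endswith(".csv"):
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise AnnotationError("annotation CSV has no data row")
        row = rows[0]
        missing = [f for f in _CSV_FIELDS if f not in row or row[f] in (None, "")]
        if missing:
            raise AnnotationError(f"annotation CSV missing field(s) {missing}")
        try:
            vals = {f: float(row[f]) for f in _CSV_FIELDS}
        except ValueError as exc:
            raise AnnotationError(f"malformed annotation CSV: {exc}") from exc
        return AnnotationSet(
            line_left=ImageLine(
                vals["left_u1"], vals["left_v1"], vals["left_u2"], vals["left_v2"]
            ),
            line_right=ImageLine(
                vals["right_u1"], vals["right_v1"], vals["right_u2"], vals["right_v2"]
            ),
            near_row_v=vals["near_row_v"],
            far_row_v=vals["far_row_v"],
            width_px=int(vals["width_px"]),
            height_px=int(vals["height_px"]),
        )
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"malformed annotation JSON: {exc}") from exc
    return _ann_from_dict(data)


def write_annotation(ann: AnnotationSet, path: Union[str, os.PathLike]) -> None:
    """Write an annotation set (format chosen by file suffix)."""
    path = os.fspath(path)
    if path.endswith(".csv"):
        line_l, line_r = ann.line_left, ann.line_right
        row = {
            "width_px": ann.width_px,
            "height_px": ann.height_px,
            "left_u1": line_l.u1,
            "left_v1": line_l.v1,
            "left_u2": line_l.u2,
            "left_v2": line_l.v2,
            "right_u1": line_r.u1,
            "right_v1": line_r.v1,
            "right_u2": line_r.u2,
            "right_v2": line_r.v2,
            "near_row_v": ann.near_row_v,
            "far_row_v": ann.far_row_v,
        }
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            writer.writeheader()
            writer.writerow(row)
        return
    with open(path, "w") as fh:
        json.dump(_ann_to_dict(ann), fh, indent=2)
        fh.write("\n")
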