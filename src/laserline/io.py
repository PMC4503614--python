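"""Configuration, measurement and report file I/O.

Rig/camera configuration (YAML or JSON)::

    alpha_h_deg: 50.43
    alpha_v_deg: 29.67
    image_width_px: 1280
    image_height_px: 800
    laser_separation_cm: 67.0
    laser_separation_sigma_cm: 0.5   # optional, default 0.5

Measurement files are JSON objects or single-row CSVs with the fields
``n_prime, n_dprime, n0, n1, n2, m0, m`` (pixels, real-valued).
"""

from __future__ import annotations

import csv
import json
import os
from typing import Union

import yaml

from .exceptions import ConfigError
from .models import CameraIntrinsics, ForwardScene, ImageMeasurements, LaserRig

_MEAS_FIELDS = ("n_prime", "n_dprime", "n0", "n1", "n2", "m0", "m")

PathLike = Union[str, os.PathLike]


def _load_mapping(path: PathLike) -> dict:
    path = os.fspath(path)
    with open(path) as fh:
        try:
            if path.endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must hold a mapping at the top level")
    return data


def _require(data: dict, key: str, path: PathLike) -> object:
    if key not in data:
        raise ConfigError(f"{os.fspath(path)} is missing required key '{key}'")
    return data[key]


def read_rig_config(path: PathLike) -> tuple[CameraIntrinsics, LaserRig]:
    """Read a camera + laser-rig configuration file."""
    data = _load_mapping(path)
    try:
        cam = CameraIntrinsics(
            alpha_h_deg=float(_require(data, "alpha_h_deg", path)),
            alpha_v_deg=float(_require(data, "alpha_v_deg", path)),
            width_px=int(_require(data, "image_width_px", path)),
            height_px=int(_require(data, "image_height_px", path)),
        )
        rig = LaserRig(
            separation_cm=float(_require(data, "laser_separation_cm", path)),
            separation_sigma_cm=float(data.get("laser_separation_sigma_cm", 0.5)),
            left_offset_cm=(
                float(data["laser_left_offset_cm"])
                if "laser_left_offset_cm" in data
                else None
            ),
            right_offset_cm=(
                float(data["laser_right_offset_cm"])
                if "laser_right_offset_cm" in data
                else None
            ),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {os.fspath(path)}: {exc}") from exc
    return cam, rig


def read_measurements(path: PathLike) -> ImageMeasurements:
    """Read a measurement file (JSON object or single-row CSV)."""
    path = os.fspath(path)
    if path.endswith(".csv"):
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ConfigError(f"{path} has no data row")
        data: dict = rows[0]
    else:
        data = _load_mapping(path)
    missing = [f for f in _MEAS_FIELDS if f not in data or data[f] in (None, "")]
    if missing:
        raise ConfigError(f"{path} is missing measurement field(s) {missing}")
    try:
        values = {f: float(data[f]) for f in _MEAS_FIELDS}
        return ImageMeasurements(**values)
    except ValueError as exc:
        raise ConfigError(f"invalid measurements in {path}: {exc}") from exc


def write_measurements(meas: ImageMeasurements, path: PathLike) -> None:
    path = os.fspath(path)
    data = {f: getattr(meas, f) for f in _MEAS_FIELDS}
    if path.endswith(".csv"):
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_MEAS_FIELDS))
            writer.writeheader()
            writer.writerow(data)
        return
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")


def read_scene_config(path: PathLike) -> ForwardScene:
    """Read a forward-model scene configuration (YAML/JSON).

    Keys: ``camera`` (the four intrinsics keys above), ``height_cm``,
    ``tilt_deg``, ``pan_deg``, ``left_offset_cm``, ``right_offset_cm``,
    optional ``ground_slope_deg``.
    """
    import math

    data = _load_mapping(path)
    cam_spec = _require(data, "camera", path)
    if not isinstance(cam_spec, dict):
        raise ConfigError(f"'camera' in {os.fspath(path)} must be a mapping")
    try:
        cam = CameraIntrinsics(
            alpha_h_deg=float(_require(cam_spec, "alpha_h_deg", path)),
            alpha_v_deg=float(_require(cam_spec, "alpha_v_deg", path)),
            width_px=int(_require(cam_spec, "image_width_px", path)),
            height_px=int(_require(cam_spec, "image_height_px", path)),
        )
        return ForwardScene(
            camera=cam,
            height_cm=float(_require(data, "height_cm", path)),
            tilt_rad=math.radians(float(_require(data, "tilt_deg", path))),
            pan_rad=math.radians(float(_require(data, "pan_deg", path))),
            left_offset_cm=float(_require(data, "left_offset_cm", path)),
            right_offset_cm=float(_require(data, "right_offset_cm", path)),
            ground_slope_rad=math.radians(float(data.get("ground_slope_deg", 0.0))),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {os.fspath(path)}: {exc}") from exc


def write_json(data: dict, path: PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_flat_csv(data: dict, path: PathLike) -> None:
    """Write a flat mapping as a one-row CSV."""
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(data))
        writer.writeheader()
        writer.writerow(data)
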