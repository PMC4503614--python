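import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laserline import CameraIntrinsics, ForwardScene, ImageMeasurements, LaserRig
from laserline import forward

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hd_camera() -> CameraIntrinsics:
    """The validation still's camera: HD frame, 50.43 x 29.67 degrees."""
    return CameraIntrinsics(
        alpha_h_deg=50.43, alpha_v_deg=29.67, width_px=1280, height_px=800
    )


@pytest.fixture(scope="session")
def survey_rig() -> LaserRig:
    """67 cm laser separation, 0.5 cm calibration uncertainty."""
    return LaserRig(separation_cm=67.0, separation_sigma_cm=0.5)


@pytest.fixture(scope="session")
def validation_measurements() -> ImageMeasurements:
    """Pixel measurements of the in situ validation still."""
    return ImageMeasurements(
        n_prime=312, n_dprime=232, n0=465, n1=52, n2=29, m0=367, m=143
    )


def make_scene(
    cam: CameraIntrinsics,
    tilt_deg: float,
    pan_deg: float,
    height_cm: float,
    left_offset_cm: float = 33.0,
    right_offset_cm: float = 34.0,
    ground_slope_deg: float = 0.0,
) -> ForwardScene:
    return ForwardScene(
        camera=cam,
        height_cm=height_cm,
        tilt_rad=math.radians(tilt_deg),
        pan_rad=math.radians(pan_deg),
        left_offset_cm=left_offset_cm,
        right_offset_cm=right_offset_cm,
        ground_slope_rad=math.radians(ground_slope_deg),
    )


def reference_rows(scene: ForwardScene) -> tuple[float, float]:
    """Near/far reference rows safely below the vanishing point."""
    big_m = scene.camera.height_px
    v_v = forward.vanishing_point_raster(scene)[1]
    near = 0.92 * big_m
    far = max(0.45 * big_m, v_v + 0.12 * big_m)
    return near, far


def random_scene(
    cam: CameraIntrinsics,
    rng: np.random.Generator,
    tilt_range=(2.0, 45.0),
    pan_range=(-20.0, 20.0),
    height_range=(50.0, 400.0),
    separation_cm: float = 67.0,
) -> ForwardScene:
    left = rng.uniform(0.3, 0.7) * separation_cm
    return make_scene(
        cam,
        tilt_deg=rng.uniform(*tilt_range),
        pan_deg=rng.uniform(*pan_range),
        height_cm=rng.uniform(*height_range),
        left_offset_cm=left,
        right_offset_cm=separation_cm - left,
    )
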