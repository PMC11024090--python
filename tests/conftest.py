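"""Shared fixtures: rendered scenes and calibration sets, cached per session.

The expensive artefacts (full-resolution scene renders, checkerboard sets,
calibration solutions) are session-scoped so unit tests and the acceptance
suite share one computation.
"""

import numpy as np
import pytest

from reefwarp.calibration import CameraModel, calibrate_camera
from reefwarp.config import PipelineConfig
from reefwarp.synthetic import (
    ScenePose,
    default_camera,
    render_calibration_set,
    render_reefscape,
)

TRUE_CAM = CameraModel(
    name="synthcam", fx=1200.0, fy=1200.0, cx=640.0, cy=480.0, image_size=(1280, 960)
)
TRUE_CAM_BARREL = CameraModel(
    name="synthcam", fx=1200.0, fy=1200.0, cx=640.0, cy=480.0, k1=-0.20, k2=0.03,
    image_size=(1280, 960),
)


def scene_family(n, base_seed=100):
    """Poses spanning pitch 10-35 deg and roll -8..+8 deg, seeded."""
    out = []
    for i in range(n):
        pitch = 10 + 25 * i / (n - 1)
        roll = -8 + 16 * ((i * 3) % n) / (n - 1)
        out.append(
            (ScenePose(camera_height=2.0, pitch=pitch, roll=roll, cam=default_camera()),
             base_seed + i)
        )
    return out


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def t1_scene():
    """The reference scene: pitch 20, roll 5, camera height 2, 1600x1200."""
    pose = ScenePose(camera_height=2.0, pitch=20.0, roll=5.0, cam=default_camera())
    img, gt = render_reefscape(pose, texture_seed=0)
    return img, gt


@pytest.fixture(scope="session")
def flat_scene():
    """Roll-free scene used by stages that assume a level horizon."""
    pose = ScenePose(camera_height=2.0, pitch=22.0, roll=0.0, cam=default_camera())
    img, gt = render_reefscape(pose, texture_seed=2)
    return img, gt


@pytest.fixture(scope="session")
def clutter_scene():
    """Scene with bright surface clutter above the horizon."""
    pose = ScenePose(camera_height=2.0, pitch=18.0, roll=3.0, cam=default_camera())
    img, gt = render_reefscape(pose, texture_seed=4, clutter=True)
    return img, gt


@pytest.fixture(scope="session")
def calib_images_zero():
    return render_calibration_set(TRUE_CAM, n_views=15, seed=3)


@pytest.fixture(scope="session")
def calib_images_barrel():
    return render_calibration_set(TRUE_CAM_BARREL, n_views=15, seed=5)


@pytest.fixture(scope="session")
def calib_model_zero(calib_images_zero):
    return calibrate_camera(calib_images_zero, (6, 9, 1.0), name="synthcam")


@pytest.fixture(scope="session")
def calib_model_barrel(calib_images_barrel):
    return calibrate_camera(calib_images_barrel, (6, 9, 1.0), name="synthcam")
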