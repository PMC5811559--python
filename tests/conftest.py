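"""Shared fixtures: synthetic scenes rendered once per session."""

import numpy as np
import pytest

from panomap.camera_geometry import CalibrationCuboid
from panomap.synthetic_fixtures import (
    AnalyticSolid,
    make_ring_camera,
    render_calibration_target,
    render_rotation_silhouettes,
)


@pytest.fixture(scope="session")
def cuboid():
    """Rabbit-scale calibration target: 1 x 1 x 2, 0.25 grid."""
    return CalibrationCuboid()


@pytest.fixture(scope="session")
def geometry_camera():
    """Corner-on view of the cuboid: both gridded faces visible."""
    return make_ring_camera(45.0, 6.0, f=400.0, image_size=(256, 256))


@pytest.fixture(scope="session")
def calibration_scene(geometry_camera, cuboid):
    """Rendered calibration image + exact junction ground truth."""
    img, truth, mask = render_calibration_target(geometry_camera, cuboid)
    return {"image": img, "truth": truth, "mask": mask,
            "camera": geometry_camera, "cuboid": cuboid}


@pytest.fixture(scope="session")
def unit_sphere():
    return AnalyticSolid("sphere", {"radius": 1.0})


@pytest.fixture(scope="session")
def sphere_stack_72(unit_sphere):
    """Standard protocol: a silhouette every 5 degrees over a full turn."""
    cam = make_ring_camera(0.0, 8.0, f=300.0, image_size=(160, 160))
    return render_rotation_silhouettes(
        unit_sphere, cam, np.arange(0.0, 360.0, 5.0)
    )


@pytest.fixture(scope="session")
def sphere_stack_toy(unit_sphere):
    """Tiny 3-view stack for brute-force comparisons."""
    cam = make_ring_camera(0.0, 8.0, f=120.0, image_size=(64, 64))
    return render_rotation_silhouettes(
        unit_sphere, cam, np.array([0.0, 50.0, 100.0])
    )
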