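"""Shared fixtures: the worked-example responder and rendered camera scenes."""

from __future__ import annotations

import numpy as np
import pytest

from visuoswarm.synthetic import (
    HONEYBEE_EXAMPLE,
    SceneSpec,
    generate_stimulus,
    multisine_spec,
    render_image_sequence,
)
from visuoswarm.tracking import make_camera_ring
from visuoswarm.trajectory import Trajectory


@pytest.fixture(scope="session")
def multisine():
    """Periodic 8-component multisine spanning 0.1-1.7 Hz, 60 s at 0.02 s."""
    return multisine_spec()


@pytest.fixture(scope="session")
def example_pair(multisine):
    """Noiseless (stimulus, animal) pair from the worked-example dynamics."""
    stim = generate_stimulus(multisine)
    animal = HONEYBEE_EXAMPLE.steady_state_response(multisine)
    return stim, animal


@pytest.fixture(scope="session")
def camera_rig():
    return make_camera_ring(3, distance=2.0, image_size=(128, 128), focal_px=180)


@pytest.fixture(scope="session")
def orbit_path():
    """Fast 3-D orbit that keeps the blob clear of its own background ghost."""
    n = 100
    t = np.arange(n) * 0.02
    f = 0.6
    path = np.column_stack(
        [
            0.30 * np.sin(2 * np.pi * f * t),
            0.22 * np.cos(2 * np.pi * f * t),
            0.12 * np.sin(4 * np.pi * f * t),
        ]
    )
    return Trajectory(path, dt=0.02)


@pytest.fixture(scope="session")
def rendered_scene(camera_rig, orbit_path):
    scene = SceneSpec(
        cameras=camera_rig,
        image_size=(128, 128),
        blob_radius=1.5,
        blob_intensity=70.0,
        background_drift=0.2,
        noise_sd=2.0,
        seed=1,
        blob_absent_frames=12,
    )
    return render_image_sequence(orbit_path, scene), scene
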