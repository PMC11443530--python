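import numpy as np
import pytest

from sparkquant.core import ImageStack
from sparkquant.synthetic import (
    ActivityProtocol,
    NoiseConfig,
    SceneConfig,
    render_movie,
    simulate_droplet_kinetics,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def step_protocol():
    """Baseline -> stimulation -> washout with a Ca²⁺ elevation window."""
    return ActivityProtocol.step(60, 10, 40, ca_window=(20, 45), ca_amplitude=3.0)


@pytest.fixture(scope="session")
def scene():
    return SceneConfig(rng_seed=7)


@pytest.fixture(scope="session")
def noise_free_scene():
    return SceneConfig(
        rng_seed=7, noise=NoiseConfig(poisson_gain=0.0, read_sigma=0.0, offset=0.0)
    )


@pytest.fixture(scope="session")
def rendered_movie(step_protocol, scene):
    """One noisy dual-reporter movie plus its schedule (session-cached)."""
    schedule = simulate_droplet_kinetics(
        step_protocol, scene, persistent_fraction=0.14
    )
    render = render_movie(schedule, step_protocol, scene, gcamp_mode=True)
    return schedule, render


def make_frame_stack(frame: np.ndarray) -> ImageStack:
    return ImageStack(
        data=np.asarray(frame, dtype=float)[None],
        axes="TYX",
        pixel_size_um=0.2,
        frame_interval_s=5.0,
    )
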