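"""Shared fixtures: small synthetic scenes kept fast enough for unit tests."""

import numpy as np
import pytest

from ommap.config import default_config
from ommap.synthetic import Patch, SceneSpec, make_movie


@pytest.fixture(scope="session")
def small_config():
    return default_config()


@pytest.fixture(scope="session")
def plane_scene():
    """Noise-free plane wave on a small grid (left-edge pacing)."""
    return SceneSpec(
        grid_rows=40,
        grid_cols=40,
        n_frames=400,
        noise_sd=0.0,
        drift_per_s=0.0,
        source="left",
        seed=11,
    )


@pytest.fixture(scope="session")
def plane_movie(plane_scene):
    return make_movie(plane_scene)


@pytest.fixture(scope="session")
def patch_scene():
    """Noise-free scene with one slow rectangular patch (25% of the grid)."""
    return SceneSpec(
        grid_rows=40,
        grid_cols=40,
        n_frames=500,
        patches=(Patch(kind="rect", speed_mps=0.1, r0=10, r1=30, c0=10, c1=30),),
        noise_sd=0.0,
        drift_per_s=0.1,
        source="left",
        seed=5,
    )


@pytest.fixture(scope="session")
def patch_movie(patch_scene):
    return make_movie(patch_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
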