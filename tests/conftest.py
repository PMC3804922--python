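"""Shared fixtures: small synthetic scenes and synthesized sessions.

The heavy session fixtures are session-scoped and use a reduced field of
view (fewer ROIs, hence smaller feature dimension) and 2 protocol
repetitions, so the whole suite stays fast while exercising the same
pipeline as the full-size geometry.
"""

import numpy as np
import pytest
from hypothesis import settings

import echoforce as ef
from echoforce import sessions

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """300x260 linear-mode scene with default noise."""
    return ef.make_scene(width=300, height=260, seed=1)


@pytest.fixture(scope="session")
def small_grid():
    return ef.build_roi_grid(ef.default_content_mask(300, 260))


@pytest.fixture(scope="session")
def clean_scene():
    """300x260 noise-free scene with reduced gain (no pixel ever clips)."""
    scene = ef.make_scene(width=300, height=260, noise_sd=0.0,
                          pattern_gain=20.0, seed=1)
    # rescale the speckle so baseline + patterns stays inside [0, 255]
    scene.canvas_baseline *= 0.8
    return scene


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise synthetic experiment (one session, 2 repetitions)."""
    scene = ef.make_scene(width=400, height=360, seed=11)
    grid = ef.build_roi_grid(ef.default_content_mask(400, 360))
    phases = sessions.synthesize_experiment(scene, fmax=20.0, n_reps=2,
                                            n_sessions=1, seed=42, grid=grid)
    return {"scene": scene, "grid": grid, **phases}


@pytest.fixture(scope="session")
def noiseless_session():
    """Noise-free linear-regime experiment (one session, 2 repetitions)."""
    scene = ef.make_scene(width=400, height=360, noise_sd=0.0, seed=11)
    grid = ef.build_roi_grid(ef.default_content_mask(400, 360))
    phases = sessions.synthesize_experiment(
        scene, fmax=20.0, n_reps=2, n_sessions=1, seed=42, grid=grid,
        lag_tau=0.0, gain_sd=0.0, noise_sd_frac=0.0)
    return {"scene": scene, "grid": grid, **phases}
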