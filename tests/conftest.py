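"""Shared fixtures: the default synthetic study and scaled-down variants.

The session-scoped ``deconv_study`` fixture runs the expensive part once —
two 500-iteration deconvolutions (30 modes and 1 mode) of the full
calibration-grid image — and every test needing deconvolved point responses
reads from it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svmpsf import (
    DeconvConfig,
    SyntheticSceneSpec,
    build_eigen_psf_model,
    deconvolve,
    generate_focus_grid,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSceneSpec:
    """The default fiber-FOV emulation: 120x120 px, 13x13 grid, noiseless."""
    return SyntheticSceneSpec()


@pytest.fixture(scope="session")
def focus_grid(default_spec):
    return generate_focus_grid(default_spec)


@pytest.fixture(scope="session")
def model(focus_grid):
    return build_eigen_psf_model(focus_grid, crop_size=15)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSceneSpec:
    """A 48x48 frame with a 5x5 grid, for brute-force oracle comparisons."""
    return SyntheticSceneSpec(
        frame_size=48,
        grid_points_per_side=5,
        core_radius=22.0,
        grid_margin=9,
    )


@pytest.fixture(scope="session")
def small_grid(small_spec):
    return generate_focus_grid(small_spec)


@pytest.fixture(scope="session")
def small_model(small_grid):
    return build_eigen_psf_model(small_grid, crop_size=15)


@pytest.fixture(scope="session")
def invariant_spec() -> SyntheticSceneSpec:
    """Spatially invariant limit: zero radial broadening, no noise."""
    return SyntheticSceneSpec(
        frame_size=64,
        grid_points_per_side=5,
        core_radius=25.0,
        radial_broadening=0.0,
        grid_margin=10,
    )


@pytest.fixture(scope="session")
def invariant_grid(invariant_spec):
    return generate_focus_grid(invariant_spec)


@pytest.fixture(scope="session")
def invariant_model(invariant_grid):
    return build_eigen_psf_model(invariant_grid, crop_size=15)


@pytest.fixture(scope="session")
def deconv_study(default_spec, focus_grid, model):
    """The paper-style deconvolution study on the recorded grid image.

    Deconvolves the sum of all 169 calibration frames for 500 iterations
    with 30 modes and with a single mode, and keeps the per-iteration
    diagnostics of both runs.
    """
    foci = focus_grid.frames.sum(axis=0)
    results = {}
    for n_modes in (30, 1):
        cfg = DeconvConfig(iterations=500, n_modes=n_modes)
        results[n_modes] = deconvolve(foci, model, cfg)
    return {
        "spec": default_spec,
        "observed": foci,
        "positions": focus_grid.position_array,
        "results": results,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
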