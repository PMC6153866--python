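"""Shared fixtures: tiny phantoms and simulations that build in seconds.

Session scope keeps the sparse projector cache warm and avoids repeating
simulations across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import lppvc
from lppvc.presets import nema_spec, thorax_spec


@pytest.fixture(scope="session")
def tiny_nema():
    return lppvc.build_nema_iq(nema_spec("tiny"))


@pytest.fixture(scope="session")
def tiny_nema_sim(tiny_nema):
    """Noise-free tiny image-quality acquisition (exact expectations)."""
    return lppvc.simulate_acquisition(
        tiny_nema.activity, tiny_nema.mu, psf_fwhm_mm=4.0, scatter_fraction=0.2,
        target_total_counts=2e5, n_angles=60, noise=False)


@pytest.fixture(scope="session")
def tiny_nema_recon(tiny_nema_sim):
    return lppvc.osem(tiny_nema_sim.counts, tiny_nema_sim.model, lppvc.ReconConfig(5, 21))


@pytest.fixture(scope="session")
def tiny_nema_noisy(tiny_nema):
    return lppvc.simulate_acquisition(
        tiny_nema.activity, tiny_nema.mu, psf_fwhm_mm=4.0, scatter_fraction=0.2,
        target_total_counts=2e6, n_angles=60, seed=7, noise=True)


@pytest.fixture(scope="session")
def tiny_thorax():
    return lppvc.build_thorax_plaque(thorax_spec("tiny"))


@pytest.fixture(scope="session")
def calibration_phantom():
    """Single 37-mm sphere centered in a water cylinder (for PSF work)."""
    spec = lppvc.default_nema_spec(grid_shape=(96, 96, 36), diameters=(37.0,),
                                   ring_radius_mm=0.0)
    return lppvc.build_nema_iq(spec)


@pytest.fixture(scope="session")
def small_model():
    """Bare system model on a small grid for projector algebra tests."""
    from lppvc.geometry import ProjectionGeometry
    from lppvc.system_model import SystemModel
    shape = (32, 32, 8)
    voxel = (2.0, 2.0, 2.0)
    geom = ProjectionGeometry.for_grid(shape, voxel, n_angles=40)
    return SystemModel(geom, shape, voxel, psf_fwhm_mm=4.0, count_scale=100.0)
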