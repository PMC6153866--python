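"""Canonical run configurations and ready-made study setups.

``tiny`` presets (64x64x16 grid, 60 views) build in seconds and drive the
test suite and examples; ``desk`` presets reproduce the full study
conditions (128x128x48 grid at 2.03 mm, 120 views, ~1e6 counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phantoms import (PhantomSpec, default_nema_spec, default_thorax_spec)
from .recon import ReconConfig


@dataclass
class RunConfig:
    """Bundled simulation + reconstruction + PVC settings for one run."""

    psf_fwhm_mm: float = 4.0
    scatter_fraction: float = 0.2
    target_total_counts: float = 1e6
    n_angles: int = 120
    seed: int = 1
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(5, 21))
    segmentation: str = "ct"
    ct_threshold_hu: float = 110.0
    voi_margin_mm: float = 12.0
    nonneg: bool = True
    noise: bool = True


_SCALES = {
    "tiny": dict(grid_shape=(64, 64, 16), n_angles=60),
    "desk": dict(grid_shape=(128, 128, 48), n_angles=120),
}


def nema_spec(scale: str = "desk", **overrides) -> PhantomSpec:
    """NEMA IQ phantom spec at the named scale.

    The tiny variant keeps only the three smallest spheres on a reduced ring
    so they fit a 64-voxel grid.
    """
    p = _SCALES[scale]
    if scale == "tiny":
        return default_nema_spec(grid_shape=p["grid_shape"],
                                 diameters=(10.0, 13.0, 17.0),
                                 ring_radius_mm=30.0, **overrides)
    return default_nema_spec(grid_shape=p["grid_shape"], **overrides)


def thorax_spec(scale: str = "desk", **overrides) -> PhantomSpec:
    p = _SCALES[scale]
    if scale == "tiny":
        return default_thorax_spec(
            grid_shape=p["grid_shape"],
            positions_mm=((0.0, 14.0, 0.0), (0.0, -14.0, 4.0), (0.0, 0.0, -6.0)),
            **overrides)
    return default_thorax_spec(grid_shape=p["grid_shape"], **overrides)


def run_config(scale: str = "desk", **overrides) -> RunConfig:
    cfg = RunConfig(n_angles=_SCALES[scale]["n_angles"], **overrides)
    return cfg
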