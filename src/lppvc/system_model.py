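"""Analytic PET acquisition model.

The expected data for an activity image ``x`` (kBq/mL) are

    lambda = normalization * attenuation * c * Ray(G x) + scatter

where ``G`` is a shift-invariant isotropic Gaussian point-spread function
applied in image space, ``Ray`` the stack-of-slices parallel-beam line
integral (mm), ``attenuation`` the per-bin survival factor exp(-integral of
mu dl), and ``c`` a per-bin count scale.  ``count_scale`` is expressed as
total detected counts per kBq/mL/mm^3 of activity summed over all views, so
the full sinogram of a single unit-activity voxel totals
``count_scale * voxel_volume`` (attenuation and normalization aside).
Scatter enters as a smooth additive sinogram; counting noise is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import ProjectionGeometry, ray_transform, ray_transform_adjoint
from .volume import ImageVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Sinogram:
    """Projection-space array (n_angles x n_radial x n_slices).

    ``counts_flag`` distinguishes integer measured counts from real-valued
    expectations.  Geometry is immutable after creation.
    """

    values: np.ndarray
    geometry: ProjectionGeometry
    counts_flag: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.sino_shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sino_shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("sinogram values must be non-negative")
        if self.counts_flag and not np.array_equal(self.values, np.rint(self.values)):
            raise ValueError("counts sinogram must hold integers")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "Sinogram":
        return replace(self, values=self.values.copy())


@dataclass
class SystemModel:
    """Acquisition physics bundle for one scan.

    ``attenuation_factors``, ``scatter`` and ``normalization`` are
    sinogram-shaped; ``None`` means all-ones (attenuation, normalization)
    or all-zeros (scatter).  The model also carries the image grid it maps
    from, so projections and adjoints need no extra arguments.
    """

    geometry: ProjectionGeometry
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    psf_fwhm_mm: float
    attenuation_factors: Sinogram | None = None
    scatter: Sinogram | None = None
    normalization: Sinogram | None = None
    count_scale: float = 1.0

    def __post_init__(self):
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        for name in ("attenuation_factors", "scatter", "normalization"):
            s = getattr(self, name)
            if s is not None and s.geometry != self.geometry:
                raise ValueError(f"{name} geometry does not match model geometry")
        att = self.attenuation_factors
        if att is not None and (np.any(att.values <= 0) or np.any(att.values > 1 + 1e-12)):
            raise ValueError("attenuation factors must lie in (0, 1]")
        if self.normalization is not None and np.any(self.normalization.values <= 0):
            raise ValueError("normalization must be positive")

    # -- helpers -----------------------------------------------------------
    @property
    def scale_per_bin(self) -> float:
        g = self.geometry
        return self.count_scale / g.n_angles * g.radial_bin_mm * g.slice_thickness_mm

    def _att_norm(self) -> np.ndarray | float:
        a = 1.0 if self.attenuation_factors is None else self.attenuation_factors.values
        n = 1.0 if self.normalization is None else self.normalization.values
        out = a * n
        return out

    def _sigma_vox(self) -> tuple[float, float, float]:
        return tuple(self.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in self.voxel_size_mm)

    def blur(self, values: np.ndarray) -> np.ndarray:
        """Apply the (self-adjoint) Gaussian PSF in image space."""
        if self.psf_fwhm_mm == 0:
            return values
        return ndimage.gaussian_filter(values, self._sigma_vox(), mode="constant")

    def with_fwhm(self, fwhm_mm: float) -> "SystemModel":
        return replace(self, psf_fwhm_mm=float(fwhm_mm))

    def scatter_values(self) -> np.ndarray:
        if self.scatter is None:
            return np.zeros(self.geometry.sino_shape)
        return self.scatter.values


def forward_project(activity: ImageVolume | np.ndarray, model: SystemModel,
                    include_scatter: bool = True,
                    slice_range: tuple[int, int] | None = None) -> Sinogram:
    """Expected sinogram of an activity image under the system model.

    Linear in the activity when ``include_scatter=False`` (or the scatter is
    held fixed).  ``slice_range`` restricts the ray transform to slices whose
    blurred activity can be non-zero (a pure speed device for sparse inputs).
    """
    values = activity.values if isinstance(activity, ImageVolume) else np.asarray(activity)
    if values.shape != model.grid_shape:
        raise ValueError(f"activity grid {values.shape} does not match model grid {model.grid_shape}")
    blurred = model.blur(values)
    p = ray_transform(blurred, model.geometry, model.voxel_size_mm, slice_range=slice_range)
    lam = model._att_norm() * (model.scale_per_bin * p)
    if include_scatter and model.scatter is not None:
        lam = lam + model.scatter.values
    return Sinogram(lam, model.geometry, counts_flag=False)


def back_project(sino: Sinogram | np.ndarray, model: SystemModel) -> ImageVolume:
    """Exact adjoint of the (scatter-free) forward projector."""
    values = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
    if values.shape != model.geometry.sino_shape:
        raise ValueError("sinogram shape does not match model geometry")
    weighted = model._att_norm() * values * model.scale_per_bin
    img = ray_transform_adjoint(weighted, model.geometry, model.grid_shape, model.voxel_size_mm)
    img = model.blur(img)
    from .volume import centered_grid
    return ImageVolume(img, model.voxel_size_mm,
                       centered_grid(model.grid_shape, model.voxel_size_mm), role="activity")


def compute_attenuation_factors(mu: ImageVolume, geometry: ProjectionGeometry) -> Sinogram:
    """Per-bin survival factors exp(-integral of mu dl) along each ray."""
    if mu.role != "mu":
        raise ValueError(f"expected a mu volume, got role {mu.role!r}")
    if np.any(mu.values < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    line_int = ray_transform(mu.values, geometry, mu.voxel_size_mm)
    return Sinogram(np.exp(-line_int), geometry)


def estimate_scatter(trues: Sinogram, scatter_fraction: float,
                     kernel_fwhm_mm: float = 80.0) -> Sinogram:
    """Smooth additive scatter estimate from the unscattered trues.

    The trues sinogram is smoothed with a wide Gaussian kernel along the
    radial and axial directions and rescaled so the scatter total equals
    SF/(1-SF) times the trues total — i.e. scatter makes up the declared
    fraction of all detected events.  This is a convolution surrogate for a
    full single-scatter simulation; its contract is only that the scatter is
    a smooth, non-negative, additive sinogram term.
    """
    if not (0.0 <= scatter_fraction < 1.0):
        raise ValueError("scatter fraction must lie in [0, 1)")
    if scatter_fraction == 0.0:
        return Sinogram(np.zeros(trues.geometry.sino_shape), trues.geometry)
    g = trues.geometry
    sigma_r = kernel_fwhm_mm * FWHM_TO_SIGMA / g.radial_bin_mm
    sigma_z = kernel_fwhm_mm * FWHM_TO_SIGMA / g.slice_thickness_mm
    smooth = ndimage.gaussian_filter(trues.values, (0.0, sigma_r, sigma_z), mode="nearest")
    total = smooth.sum()
    target = scatter_fraction / (1.0 - scatter_fraction) * trues.values.sum()
    if total > 0:
        smooth *= target / total
    return Sinogram(np.maximum(smooth, 0.0), g)


def add_poisson_noise(expectations: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per bin, reproducible for a fixed seed."""
    if np.any(expectations.values < 0):
        raise ValueError("expectations must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expectations.values).astype(float)
    return Sinogram(counts, expectations.geometry, counts_flag=True)


@dataclass
class SimulationResult:
    counts: Sinogram
    expectations: Sinogram
    model: SystemModel
    seed: int | None


def simulate_acquisition(activity: ImageVolume, mu: ImageVolume | None, *,
                         psf_fwhm_mm: float, scatter_fraction: float = 0.2,
                         target_total_counts: float | None = 1e6,
                         count_scale: float | None = None,
                         n_angles: int = 120, seed: int | None = 1,
                         noise: bool = True,
                         geometry: ProjectionGeometry | None = None) -> SimulationResult:
    """Simulate one acquisition: PSF blur, projection, attenuation, scatter,
    Poisson counting noise.

    Either ``target_total_counts`` (the count scale is calibrated so the
    expected total over the sinogram matches it) or an explicit
    ``count_scale`` must be given.  ``noise=False`` returns the noise-free
    expectations as the "counts" (flagged as expectations).
    """
    if geometry is None:
        geometry = ProjectionGeometry.for_grid(activity.shape, activity.voxel_size_mm, n_angles)
    att = None
    if mu is not None:
        activity.check_companion(mu)
        att = compute_attenuation_factors(mu, geometry)
    model = SystemModel(geometry, activity.shape, activity.voxel_size_mm,
                        psf_fwhm_mm=psf_fwhm_mm, attenuation_factors=att, count_scale=1.0)
    trues_unit = forward_project(activity, model, include_scatter=False)
    if count_scale is None:
        if target_total_counts is None:
            raise ValueError("give either target_total_counts or count_scale")
        denom = trues_unit.total / (1.0 - scatter_fraction)
        if denom <= 0:
            raise ValueError("activity projects to zero counts; cannot calibrate count scale")
        count_scale = float(target_total_counts) / denom
    model = replace(model, count_scale=float(count_scale))
    trues = Sinogram(trues_unit.values * count_scale, geometry)
    scatter = estimate_scatter(trues, scatter_fraction)
    model = replace(model, scatter=scatter)
    expectations = Sinogram(trues.values + scatter.values, geometry)
    if noise:
        if seed is None:
            raise ValueError("a seed is required when noise=True")
        counts = add_poisson_noise(expectations, seed)
    else:
        counts = expectations.copy()
    return SimulationResult(counts=counts, expectations=expectations, model=model, seed=seed)
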