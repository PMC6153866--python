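"""OSEM reconstruction with attenuation/normalization as multiplicative and
scatter as additive corrections, optional resolution modeling and Gaussian
post-filtering.

The update over ordered subsets S of views is the classical

    x <- x / (A_S^T 1) * A_S^T( y_S / (A_S x + s_S) )

with A the attenuated, normalized (and, when resolution modeling is on,
PSF-blurred) projector, s the additive scatter, and all divisions guarded.
Angles are assigned to subsets round-robin, so subset sizes differ by at
most one when the subset count does not divide the number of views.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import system_matrix
from .system_model import FWHM_TO_SIGMA, Sinogram, SystemModel
from .volume import ImageVolume, centered_grid

EPS = 1e-10
SENS_FREEZE_REL = 1e-8


@dataclass
class ReconConfig:
    n_iterations: int = 5
    n_subsets: int = 21
    psf_in_recon: bool = False
    psf_fwhm_mm: float = 0.0
    postfilter_fwhm_mm: float = 0.0

    def __post_init__(self):
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be positive")
        if self.psf_fwhm_mm < 0 or self.postfilter_fwhm_mm < 0:
            raise ValueError("FWHM values must be >= 0")


def _recon_blur(values, fwhm_mm, voxel_size_mm):
    if fwhm_mm == 0:
        return values
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm)
    return ndimage.gaussian_filter(values, sigma, mode="constant")


def osem(counts: Sinogram, model: SystemModel, config: ReconConfig,
         initial: ImageVolume | None = None) -> ImageVolume:
    """OSEM reconstruction of a counts sinogram.

    The recon-side projector uses ``config.psf_fwhm_mm`` when
    ``config.psf_in_recon`` is set and no blur otherwise — reconstructing
    data from a blurred system without resolution modeling yields the usual
    resolution-limited image, with it the resolution-recovered one.  The
    configured post-filter is applied to the final image.
    """
    geom = model.geometry
    if counts.geometry != geom:
        raise ValueError("counts geometry does not match model")
    nx, ny, nz = model.grid_shape
    if config.n_subsets > geom.n_angles:
        raise ValueError("more subsets than views: empty subset")
    fwhm = config.psf_fwhm_mm if config.psf_in_recon else 0.0
    blur = lambda v: _recon_blur(v, fwhm, model.voxel_size_mm)

    A = system_matrix(geom, nx, ny, model.voxel_size_mm)
    att_norm = model._att_norm()
    if np.isscalar(att_norm):
        att_norm = np.full(geom.sino_shape, float(att_norm))
    att_norm_flat = (att_norm * model.scale_per_bin).reshape(geom.n_angles * geom.n_radial, nz)
    y_flat = counts.values.reshape(-1, nz)
    s_flat = model.scatter_values().reshape(-1, nz)

    subsets = []
    for s in range(config.n_subsets):
        angle_idx = np.arange(s, geom.n_angles, config.n_subsets)
        rows = (angle_idx[:, None] * geom.n_radial + np.arange(geom.n_radial)[None, :]).ravel()
        A_s = A[rows]
        sens = blur((A_s.T @ att_norm_flat[rows]).reshape(nx, ny, nz))
        subsets.append((rows, A_s, sens))
    sens_max = max(s[2].max() for s in subsets)
    freeze = sens_max * SENS_FREEZE_REL

    if initial is not None:
        x = np.asarray(initial.values, dtype=float).copy()
        if x.shape != model.grid_shape:
            raise ValueError("initial image grid mismatch")
    else:
        # uniform start scaled so the model total matches the measured total
        x = np.ones((nx, ny, nz))
        fp_tot = float((att_norm_flat * (A @ blur(x).reshape(nx * ny, nz))).sum())
        scale = max(y_flat.sum() - s_flat.sum(), 0.0) / max(fp_tot, EPS)
        x *= max(scale, EPS)

    for _ in range(config.n_iterations):
        for rows, A_s, sens in subsets:
            fp = att_norm_flat[rows] * (A_s @ blur(x).reshape(nx * ny, nz)) + s_flat[rows]
            ratio = y_flat[rows] / np.maximum(fp, EPS)
            corr = blur((A_s.T @ (att_norm_flat[rows] * ratio)).reshape(nx, ny, nz))
            with np.errstate(invalid="ignore", divide="ignore"):
                upd = np.where(sens > freeze, corr / np.maximum(sens, EPS), 0.0)
            x = x * upd
    x = np.maximum(x, 0.0)

    img = ImageVolume(x, model.voxel_size_mm,
                      centered_grid(model.grid_shape, model.voxel_size_mm), role="activity")
    if config.postfilter_fwhm_mm > 0:
        img = gaussian_postfilter(img, config.postfilter_fwhm_mm)
    return img


def gaussian_postfilter(img: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Isotropic Gaussian smoothing; conserves total activity for sources
    away from the grid boundary."""
    if fwhm_mm < 0:
        raise ValueError("post-filter FWHM must be >= 0")
    if fwhm_mm == 0:
        return img.copy()
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in img.voxel_size_mm)
    return img.with_values(ndimage.gaussian_filter(img.values, sigma, mode="constant"))


def poisson_loglik(counts: Sinogram, model: SystemModel, img: ImageVolume,
                   psf_fwhm_mm: float | None = None) -> float:
    """Poisson log-likelihood sum(y log lam - lam), up to the y! constant.

    ``psf_fwhm_mm`` overrides the model blur for matching a recon config.
    """
    m = model if psf_fwhm_mm is None else model.with_fwhm(psf_fwhm_mm)
    from .system_model import forward_project
    lam = np.maximum(forward_project(img, m).values, EPS)
    y = counts.values
    return float((y * np.log(lam) - lam).sum())
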