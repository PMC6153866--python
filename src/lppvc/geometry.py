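"""Parallel-beam projection geometry and the sparse ray-transform matrix.

The acquisition model is a stack-of-slices 2D parallel-beam geometry: every
axial slice is projected independently onto ``n_angles`` views uniformly
spaced over 180 degrees, each with ``n_radial`` radial bins.  The ray
transform is materialized once per 2D geometry as a sparse matrix of sampled
line integrals (Joseph-style: points every half voxel along each ray,
bilinear interpolation weights, weighted by the step length in mm).  The
matrix is shared by all slices and cached per geometry, and its transpose is
the exact adjoint used by the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}


@dataclass(frozen=True)
class ProjectionGeometry:
    """Sinogram geometry: views over 180 deg x radial bins x axial slices."""

    n_angles: int
    n_radial: int
    radial_bin_mm: float
    n_slices: int
    slice_thickness_mm: float

    def __post_init__(self):
        if self.n_angles < 1 or self.n_radial < 1 or self.n_slices < 1:
            raise ValueError("geometry dimensions must be positive")
        if self.radial_bin_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("bin sizes must be positive")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_offsets_mm(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_bin_mm

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial, self.n_slices)

    @classmethod
    def for_grid(cls, shape, voxel_size_mm, n_angles: int = 120) -> "ProjectionGeometry":
        """Default geometry for an image grid: radial bin = transaxial voxel."""
        nx, ny, nz = shape
        return cls(
            n_angles=n_angles,
            n_radial=max(nx, ny),
            radial_bin_mm=float(voxel_size_mm[0]),
            n_slices=nz,
            slice_thickness_mm=float(voxel_size_mm[2]),
        )


def system_matrix(geom: ProjectionGeometry, nx: int, ny: int, voxel_size_mm,
                  step_fraction: float = 0.5) -> sparse.csr_matrix:
    """Sparse 2D ray-transform matrix, (n_angles*n_radial) x (nx*ny).

    Row ``a * n_radial + r`` holds the sampled line integral (mm) of the ray
    at view ``a`` and radial offset ``r`` through a single transaxial slice.
    Cached per geometry; building the 128-grid default takes a few seconds.
    """
    vx, vy = float(voxel_size_mm[0]), float(voxel_size_mm[1])
    key = (geom.n_angles, geom.n_radial, round(geom.radial_bin_mm, 9),
           nx, ny, round(vx, 9), round(vy, 9), round(step_fraction, 9))
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]

    step = step_fraction * min(vx, vy)
    half_diag = 0.5 * np.hypot(nx * vx, ny * vy)
    t = np.arange(-half_diag - step, half_diag + step, step)
    s = geom.radial_offsets_mm
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    rows_all, cols_all, vals_all = [], [], []
    for a, theta in enumerate(geom.angles_rad):
        u = np.array([np.cos(theta), np.sin(theta)])   # radial direction
        v = np.array([-np.sin(theta), np.cos(theta)])  # along-ray direction
        # sample positions: (n_radial, n_t, 2)
        px = s[:, None] * u[0] + t[None, :] * v[0]
        py = s[:, None] * u[1] + t[None, :] * v[1]
        fx = px / vx + cx
        fy = py / vy + cy
        i0 = np.floor(fx).astype(np.int64)
        j0 = np.floor(fy).astype(np.int64)
        dx = fx - i0
        dy = fy - j0
        valid = (i0 >= 0) & (i0 < nx - 1) & (j0 >= 0) & (j0 < ny - 1)
        if not np.any(valid):
            continue
        ridx = np.broadcast_to(np.arange(geom.n_radial)[:, None], fx.shape)
        base_rows = (a * geom.n_radial + ridx)[valid]
        i0v, j0v, dxv, dyv = i0[valid], j0[valid], dx[valid], dy[valid]
        for di, dj, w in (
            (0, 0, (1 - dxv) * (1 - dyv)),
            (1, 0, dxv * (1 - dyv)),
            (0, 1, (1 - dxv) * dyv),
            (1, 1, dxv * dyv),
        ):
            rows_all.append(base_rows)
            cols_all.append((i0v + di) * ny + (j0v + dj))
            vals_all.append(w * step)

    mat = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(geom.n_angles * geom.n_radial, nx * ny),
    ).tocsr()
    mat.sum_duplicates()
    _MATRIX_CACHE[key] = mat
    return mat


def ray_transform(image3d: np.ndarray, geom: ProjectionGeometry, voxel_size_mm,
                  slice_range: tuple[int, int] | None = None) -> np.ndarray:
    """Line integrals (value-units x mm) of a 3D image, slice by slice.

    ``slice_range=(z0, z1)`` restricts work to those slices; the rest of the
    sinogram is returned as zeros.
    """
    nx, ny, nz = image3d.shape
    A = system_matrix(geom, nx, ny, voxel_size_mm)
    out = np.zeros((geom.n_angles * geom.n_radial, nz))
    z0, z1 = slice_range if slice_range is not None else (0, nz)
    if z1 > z0:
        flat = image3d[:, :, z0:z1].reshape(nx * ny, z1 - z0)
        out[:, z0:z1] = A @ flat
    return out.reshape(geom.n_angles, geom.n_radial, nz)


def ray_transform_adjoint(sino3d: np.ndarray, geom: ProjectionGeometry,
                          grid_shape, voxel_size_mm) -> np.ndarray:
    """Exact adjoint of :func:`ray_transform` (backprojection)."""
    nx, ny, nz = grid_shape
    A = system_matrix(geom, nx, ny, voxel_size_mm)
    flat = sino3d.reshape(geom.n_angles * geom.n_radial, nz)
    return (A.T @ flat).reshape(nx, ny, nz)
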