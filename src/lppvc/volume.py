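"""Voxelized image volumes.

An :class:`ImageVolume` is a 3D array on a regular grid together with its
voxel size, physical origin and a semantic *role*: activity concentration
(kBq/mL), 511-keV linear attenuation (mm^-1), CT density (HU) or an integer
label map.  Companion volumes of one phantom share a single grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ROLES = ("activity", "mu", "hu", "label")


@dataclass
class ImageVolume:
    """3D voxel grid with spacing, origin and a semantic role.

    Parameters
    ----------
    values
        3D array.  Activity and attenuation volumes must be non-negative;
        label volumes must hold non-negative integers.
    voxel_size_mm
        Positive spacing per axis (mm).
    origin_mm
        Physical coordinate of the center of voxel (0, 0, 0).
    role
        One of ``{"activity", "mu", "hu", "label"}``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "activity"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got ndim={self.values.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be three positive values, got {self.voxel_size_mm}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in ("activity", "mu") and np.any(self.values < 0):
            raise ValueError(f"{self.role} volume must be non-negative")
        if self.role == "label":
            if not np.issubdtype(self.values.dtype, np.integer):
                ints = np.rint(self.values)
                if not np.array_equal(ints, self.values):
                    raise ValueError("label volume must hold integers")
                self.values = ints.astype(np.int32)
            if np.any(self.values < 0):
                raise ValueError("label volume must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz

    def copy(self) -> "ImageVolume":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray, role: str | None = None) -> "ImageVolume":
        return ImageVolume(values, self.voxel_size_mm, self.origin_mm, role or self.role)

    def voxel_centers_mm(self):
        """Per-axis 1D arrays of physical voxel-center coordinates (mm)."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a]
            for a in range(3)
        )

    def check_companion(self, other: "ImageVolume") -> None:
        """Raise if *other* does not live on this volume's grid."""
        if other.shape != self.shape or other.voxel_size_mm != self.voxel_size_mm:
            raise ValueError(
                f"companion volume grid mismatch: {other.shape}@{other.voxel_size_mm} "
                f"vs {self.shape}@{self.voxel_size_mm}"
            )


def centered_grid(shape, voxel_size_mm):
    """Origin placing the grid center at physical (0, 0, 0)."""
    return tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size_mm))
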