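"""Digital phantoms: NEMA image-quality, thorax with plaque-type lesions,
and a synthetic carotid section.

Each builder returns companion activity (kBq/mL), attenuation (mm^-1), CT
density (HU) and integer label volumes on one grid, plus the *intended*
(pre-rasterization) lesion activities.  Lesions are rasterized with
fractional voxel occupancy so that sub-voxel lesions conserve activity mass:
a voxel's activity is the occupancy-weighted mix of lesion and background
concentration.  For such lesions the voxelized maximum is attenuated by
occupancy, which is why the intended activities are carried separately as
the ground-truth (EXP) reference.

Phantom construction is fully deterministic for a fixed spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .volume import ImageVolume, centered_grid

MU_WATER = 0.0096   # mm^-1 at 511 keV
MU_BONE = 0.017     # mm^-1, bone / dense calcification
MU_LUNG = 0.0026    # mm^-1, inflated lung

NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
THORAX_LESION_VOLUMES_MM3 = (36.0, 31.0, 18.0)


def volume_to_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere with the given volume: d = (6V/pi)^(1/3)."""
    if volume_mm3 <= 0:
        raise ValueError("lesion volume must be positive")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


@dataclass
class LesionSpec:
    center_mm: tuple[float, float, float]
    diameter_mm: float | None = None
    volume_mm3: float | None = None
    activity_kbq_ml: float | None = None
    hu: float = 0.0
    mu: float = MU_WATER

    def __post_init__(self):
        if (self.diameter_mm is None) == (self.volume_mm3 is None):
            raise ValueError("give exactly one of diameter_mm or volume_mm3")
        if self.diameter_mm is None:
            self.diameter_mm = volume_to_diameter(self.volume_mm3)
        else:
            if self.diameter_mm <= 0:
                raise ValueError("lesion diameter must be positive")
            self.volume_mm3 = math.pi / 6.0 * self.diameter_mm ** 3


@dataclass
class PhantomSpec:
    """Declarative phantom description (see docs for the YAML schema)."""

    grid_shape: tuple[int, int, int] = (128, 128, 48)
    voxel_size_mm: tuple[float, float, float] = (2.03, 2.03, 2.03)
    background_activity: float = 4.8
    lesion_to_background: float = 4.95
    lesions: list[LesionSpec] = field(default_factory=list)
    body: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size components must be positive")
        if self.lesion_to_background <= 0:
            raise ValueError("lesion-to-background ratio must be positive")
        if self.background_activity < 0:
            raise ValueError("background activity must be non-negative")


@dataclass
class PhantomVolumes:
    """Companion volumes plus the intended ground-truth activities."""

    activity: ImageVolume
    mu: ImageVolume
    hu: ImageVolume
    label: ImageVolume
    background_activity: float
    intended: dict[int, dict[str, float]]  # label id -> {activity, diameter_mm, volume_mm3, hu}
    body_mask: np.ndarray
    reference_mask: np.ndarray | None = None

    @property
    def intended_lbr(self) -> float:
        if not self.intended:
            return 1.0
        acts = [v["activity"] for v in self.intended.values()]
        return max(acts) / self.background_activity

    def lesion_mask(self, label_id: int) -> np.ndarray:
        return self.label.values == label_id


# ---------------------------------------------------------------------------
# rasterization

def rasterize_sphere(center_mm, diameter_mm: float, grid: ImageVolume | tuple,
                     supersample: int | None = None) -> ImageVolume:
    """Fractional-occupancy rasterization of a sphere.

    Each voxel value is the fraction of its volume inside the sphere,
    estimated by ``supersample^3`` sub-voxel sampling points.  The occupancy
    sum times the voxel volume approximates the sphere volume.  The default
    sampling density adapts to the sphere size so sub-voxel lesions stay
    mass-accurate to ~1%.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if isinstance(grid, ImageVolume):
        shape, voxel, origin = grid.shape, grid.voxel_size_mm, grid.origin_mm
    else:
        shape, voxel = grid
        origin = centered_grid(shape, voxel)
    if supersample is None:
        supersample = 16 if diameter_mm < 4 * min(voxel) else 8
    r = diameter_mm / 2.0
    occ = np.zeros(shape)
    # bounding box of candidate voxels
    lo, hi = [], []
    for a in range(3):
        i_lo = int(np.floor((center_mm[a] - r - origin[a]) / voxel[a] - 0.5))
        i_hi = int(np.ceil((center_mm[a] + r - origin[a]) / voxel[a] + 0.5))
        lo.append(max(i_lo, 0))
        hi.append(min(i_hi + 1, shape[a]))
    if any(l >= h for l, h in zip(lo, hi)):
        raise ValueError("empty rasterization: sphere entirely outside grid")
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    axes = []
    for a in range(3):
        centers = origin[a] + np.arange(lo[a], hi[a]) * voxel[a]
        axes.append((centers[:, None] + sub[None, :] * voxel[a] - center_mm[a]).reshape(-1))
    dx2 = axes[0] ** 2
    dy2 = axes[1] ** 2
    dz2 = axes[2] ** 2
    inside = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r * r
    n = supersample
    block = inside.reshape(hi[0] - lo[0], n, hi[1] - lo[1], n, hi[2] - lo[2], n)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = block.mean(axis=(1, 3, 5))
    if occ.max() == 0.0:
        raise ValueError("empty rasterization: sphere entirely outside grid")
    vol = ImageVolume(occ, voxel, origin, role="activity")
    return vol


def _coordinate_grids(shape, voxel, origin):
    xs = origin[0] + np.arange(shape[0]) * voxel[0]
    ys = origin[1] + np.arange(shape[1]) * voxel[1]
    zs = origin[2] + np.arange(shape[2]) * voxel[2]
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _cylinder_mask(shape, voxel, origin, center_mm, radius_mm, half_height_mm,
                   semi_axes_mm=None, axis: int = 2):
    """Axis-aligned (default z) elliptic cylinder mask."""
    X, Y, Z = _coordinate_grids(shape, voxel, origin)
    coords = [X - center_mm[0], Y - center_mm[1], Z - center_mm[2]]
    tr = [c for a, c in enumerate(coords) if a != axis]
    if semi_axes_mm is None:
        semi_axes_mm = (radius_mm, radius_mm)
    radial = (tr[0] / semi_axes_mm[0]) ** 2 + (tr[1] / semi_axes_mm[1]) ** 2
    return (radial <= 1.0) & (np.abs(coords[axis]) <= half_height_mm)


# ---------------------------------------------------------------------------
# phantom builders

def _assemble(spec: PhantomSpec, body_mask, body_mu, body_hu, lesions, lesion_ids,
              reference_mask=None, body_activity=None) -> PhantomVolumes:
    """Mass-preserving composition of background body + occupancy lesions."""
    shape, voxel = spec.grid_shape, spec.voxel_size_mm
    origin = centered_grid(shape, voxel)
    bg = spec.background_activity if body_activity is None else body_activity
    activity = np.where(body_mask, float(bg), 0.0)
    mu = np.where(body_mask, body_mu, 0.0)
    hu = np.where(body_mask, body_hu, -1000.0)
    label = np.zeros(shape, dtype=np.int32)
    intended: dict[int, dict[str, float]] = {}

    occupancy_sum = np.zeros(shape)
    for lesion, lid in zip(lesions, lesion_ids):
        if lesion.activity_kbq_ml is None:
            lesion.activity_kbq_ml = spec.lesion_to_background * spec.background_activity
        occ = rasterize_sphere(lesion.center_mm, lesion.diameter_mm, (shape, voxel)).values
        if np.any((occupancy_sum > 0) & (occ > 0)):
            raise ValueError("overlapping lesions in phantom spec")
        occupancy_sum += occ
        activity = activity * (1 - occ) + occ * lesion.activity_kbq_ml
        mu = mu * (1 - occ) + occ * lesion.mu
        # sub-voxel lesions never reach 50% occupancy; label/HU any touched voxel
        occ_thresh = 0.5 if occ.max() > 0.5 else 0.0
        hu = np.where(occ > occ_thresh, lesion.hu, hu)
        label[occ > occ_thresh] = lid
        intended[lid] = {
            "activity": float(lesion.activity_kbq_ml),
            "diameter_mm": float(lesion.diameter_mm),
            "volume_mm3": float(lesion.volume_mm3),
            "hu": float(lesion.hu),
        }

    mk = lambda v, role: ImageVolume(v, voxel, origin, role=role)
    return PhantomVolumes(
        activity=mk(activity, "activity"), mu=mk(mu, "mu"),
        hu=mk(hu, "hu"), label=mk(label, "label"),
        background_activity=float(bg), intended=intended,
        body_mask=body_mask, reference_mask=reference_mask,
    )


def default_nema_spec(grid_shape=(128, 128, 48), voxel_size_mm=(2.03, 2.03, 2.03),
                      diameters=NEMA_SPHERE_DIAMETERS_MM, ring_radius_mm=57.2,
                      background_activity=4.8, ratio=4.95) -> PhantomSpec:
    """Six hot spheres on a ring in a water cylinder (image-quality layout)."""
    lesions = []
    n = len(diameters)
    for k, d in enumerate(diameters):
        ang = 2 * math.pi * k / n
        lesions.append(LesionSpec(
            center_mm=(ring_radius_mm * math.cos(ang), ring_radius_mm * math.sin(ang), 0.0),
            diameter_mm=d, hu=300.0, mu=MU_WATER))
    return PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       background_activity=background_activity,
                       lesion_to_background=ratio, lesions=lesions)


def _body_param(spec: PhantomSpec, key: str, default):
    for prim in spec.body:
        if key in prim:
            return prim[key]
    return default


def build_nema_iq(spec: PhantomSpec | None = None, body_radius_mm: float | None = None) -> PhantomVolumes:
    """NEMA-style image-quality phantom: hot spheres in a warm water body.

    The body radius defaults to 110 mm (human-torso scale) but shrinks
    automatically to fit reduced grids.
    """
    spec = spec or default_nema_spec()
    shape, voxel = spec.grid_shape, spec.voxel_size_mm
    if body_radius_mm is None:
        fit = min(shape[0] * voxel[0], shape[1] * voxel[1]) / 2.0 - 2 * voxel[0]
        body_radius_mm = _body_param(spec, "radius_mm", min(110.0, fit))
    origin = centered_grid(shape, voxel)
    half_height = (shape[2] * voxel[2]) / 2.0 - voxel[2]
    body = _cylinder_mask(shape, voxel, origin, (0, 0, 0), body_radius_mm, half_height)
    ids = list(range(1, len(spec.lesions) + 1))
    return _assemble(spec, body, MU_WATER, 0.0, spec.lesions, ids)


def default_thorax_spec(grid_shape=(128, 128, 48), voxel_size_mm=(2.03, 2.03, 2.03),
                        volumes_mm3=THORAX_LESION_VOLUMES_MM3,
                        positions_mm=((0.0, 22.0, 0.0), (-6.0, -16.0, 14.0), (8.0, -4.0, -14.0)),
                        background_activity=4.0, ratio=70.0, lesion_hu=400.0) -> PhantomSpec:
    """Thorax phantom with three sub-voxel "plaque-type" lesions.

    Lesion positions sit in the mediastinal region between the lungs; they
    are spec fields and can be moved freely.
    """
    lesions = [LesionSpec(center_mm=p, volume_mm3=v, hu=lesion_hu, mu=MU_BONE)
               for p, v in zip(positions_mm, volumes_mm3)]
    return PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       background_activity=background_activity,
                       lesion_to_background=ratio, lesions=lesions)


def build_thorax_plaque(spec: PhantomSpec | None = None,
                        body_semi_axes_mm=None,
                        lung_activity: float = 1.0) -> PhantomVolumes:
    """Human-thorax-sized body with lungs and plaque-type lesions."""
    spec = spec or default_thorax_spec()
    shape, voxel = spec.grid_shape, spec.voxel_size_mm
    origin = centered_grid(shape, voxel)
    if body_semi_axes_mm is None:
        fit_x = shape[0] * voxel[0] / 2.0 - 2 * voxel[0]
        fit_y = shape[1] * voxel[1] / 2.0 - 2 * voxel[1]
        body_semi_axes_mm = _body_param(spec, "semi_axes_mm",
                                        (min(110.0, fit_x), min(80.0, fit_y)))
    half_height = (shape[2] * voxel[2]) / 2.0 - voxel[2]
    body = _cylinder_mask(shape, voxel, origin, (0, 0, 0), None, half_height,
                          semi_axes_mm=body_semi_axes_mm)
    ids = list(range(1, len(spec.lesions) + 1))
    ph = _assemble(spec, body, MU_WATER, 0.0, spec.lesions, ids)
    # carve two lung compartments (low density, low uptake), scaled to the body
    lung_sx = 0.5 * body_semi_axes_mm[0]
    for sx in (-1, 1):
        lung = _cylinder_mask(shape, voxel, origin, (sx * lung_sx, 0.06 * body_semi_axes_mm[1], 0.0),
                              None, half_height * 0.9,
                              semi_axes_mm=(0.35 * body_semi_axes_mm[0], 0.68 * body_semi_axes_mm[1]))
        lung &= ~np.isin(ph.label.values, ids)  # never overwrite lesions
        ph.activity.values[lung] = lung_activity
        ph.mu.values[lung] = MU_LUNG
        ph.hu.values[lung] = -700.0
    return ph


def build_carotid_section(plaque_hu: float = 600.0, plaque_volume_mm3: float = 120.0,
                          plaque_activity: float | None = None,
                          background_activity: float = 1.0,
                          lesion_to_background: float = 10.0,
                          vessel_radius_mm: float = 3.5,
                          vessel_offset_mm=(20.0, 0.0),
                          plaque_center_mm: tuple[float, float, float] | None = None,
                          grid_shape=(96, 96, 48),
                          voxel_size_mm=(2.03, 2.03, 2.03)) -> PhantomVolumes:
    """Synthetic neck section with one carotid plaque lesion.

    A soft-tissue cylinder holds a vertical vessel; the plaque sits on the
    vessel wall with a configurable HU (driving the four-class calcification
    taxonomy) and volume (the patient range spans roughly 50-500 mm^3).  A
    reference mask marks an arterial background segment 10-15 mm below the
    plaque, the region used for the background mean in patient-style
    quantification.  ``plaque_volume_mm3=0`` builds the zero-lesion phantom.
    """
    lesions = []
    plaque_center = plaque_center_mm or (vessel_offset_mm[0] + vessel_radius_mm,
                                         vessel_offset_mm[1], 0.0)
    if plaque_volume_mm3 > 0:
        d = volume_to_diameter(plaque_volume_mm3)
        dist = math.hypot(plaque_center[0] - vessel_offset_mm[0],
                          plaque_center[1] - vessel_offset_mm[1])
        if dist > vessel_radius_mm + d / 2.0:
            raise ValueError("plaque lesion does not touch the vessel")
        lesions.append(LesionSpec(center_mm=plaque_center, volume_mm3=plaque_volume_mm3,
                                  activity_kbq_ml=plaque_activity, hu=plaque_hu,
                                  mu=MU_BONE if plaque_hu >= 110 else MU_WATER))
    spec = PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       background_activity=background_activity,
                       lesion_to_background=lesion_to_background, lesions=lesions)
    shape, voxel = spec.grid_shape, spec.voxel_size_mm
    origin = centered_grid(shape, voxel)
    half_height = (shape[2] * voxel[2]) / 2.0 - voxel[2]
    fit = min(shape[0] * voxel[0], shape[1] * voxel[1]) / 2.0 - 2 * voxel[0]
    body = _cylinder_mask(shape, voxel, origin, (0, 0, 0), min(70.0, fit), half_height)
    ph = _assemble(spec, body, MU_WATER, 40.0, spec.lesions, [1] if lesions else [])
    # vessel lumen: slightly elevated blood-pool signal, soft-tissue density
    vessel = _cylinder_mask(shape, voxel, origin,
                            (vessel_offset_mm[0], vessel_offset_mm[1], 0.0),
                            vessel_radius_mm, half_height)
    vessel &= ph.label.values == 0
    ph.activity.values[vessel] = background_activity
    ph.hu.values[vessel] = 45.0
    # arterial reference segment 10-15 mm below the plaque
    X, Y, Z = _coordinate_grids(shape, voxel, origin)
    below = (Z <= plaque_center[2] - 10.0) & (Z >= plaque_center[2] - 15.0)
    ph.reference_mask = vessel & below
    return ph
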