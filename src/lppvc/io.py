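"""File formats: NIfTI-1 volumes and npz sinograms, each with a JSON sidecar.

Volumes round-trip through NIfTI-1 with the voxel size in the header and the
semantic role (activity/mu/hu/label) in ``<stem>.json``.  Sinograms are
stored as a compressed ``.npz`` array with geometry, counts flag and seed in
the sidecar; read-back validates the array against the sidecar geometry.
Phantom specs are declarative YAML (see the README for the schema).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import ProjectionGeometry
from .phantoms import LesionSpec, PhantomSpec
from .system_model import Sinogram
from .volume import ImageVolume


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")


def write_volume(path, vol: ImageVolume) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    data = vol.values.astype(np.int32 if vol.role == "label" else np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    _sidecar(path).write_text(json.dumps({
        "role": vol.role,
        "voxel_size_mm": list(vol.voxel_size_mm),
        "origin_mm": list(vol.origin_mm),
    }, indent=1))
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    meta = json.loads(_sidecar(path).read_text())
    voxel = tuple(meta.get("voxel_size_mm") or img.header.get_zooms()[:3])
    return ImageVolume(data, voxel, tuple(meta.get("origin_mm", (0, 0, 0))),
                       role=meta.get("role", "activity"))


def write_sinogram(path, sino: Sinogram, seed: int | None = None) -> Path:
    path = Path(path)
    np.savez_compressed(path, values=sino.values)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    g = sino.geometry
    _sidecar(path).write_text(json.dumps({
        "n_angles": g.n_angles, "n_radial": g.n_radial,
        "radial_bin_mm": g.radial_bin_mm,
        "n_slices": g.n_slices, "slice_thickness_mm": g.slice_thickness_mm,
        "counts_flag": sino.counts_flag, "seed": seed,
    }, indent=1))
    return path


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    values = np.load(path)["values"]
    meta = json.loads(_sidecar(path).read_text())
    geom = ProjectionGeometry(meta["n_angles"], meta["n_radial"], meta["radial_bin_mm"],
                              meta["n_slices"], meta["slice_thickness_mm"])
    if values.shape != geom.sino_shape:
        raise ValueError(f"sinogram array {values.shape} does not match sidecar geometry "
                         f"{geom.sino_shape}")
    return Sinogram(values, geom, counts_flag=bool(meta.get("counts_flag", False)))


def read_phantom_spec(path) -> PhantomSpec:
    raw = yaml.safe_load(Path(path).read_text())
    lesions = [LesionSpec(
        center_mm=tuple(l["center_mm"]),
        diameter_mm=l.get("diameter_mm"),
        volume_mm3=l.get("volume_mm3"),
        activity_kbq_ml=l.get("activity_kbq_ml"),
        hu=l.get("hu", 0.0),
        mu=l.get("mu", 0.0096),
    ) for l in raw.get("lesions", [])]
    return PhantomSpec(
        grid_shape=tuple(raw.get("grid_shape", (128, 128, 48))),
        voxel_size_mm=tuple(raw.get("voxel_size_mm", (2.03, 2.03, 2.03))),
        background_activity=raw.get("background_activity", 4.8),
        lesion_to_background=raw.get("lesion_to_background", 4.95),
        lesions=lesions,
        seed=raw.get("seed", 0),
    )


def write_phantom_spec(path, spec: PhantomSpec) -> Path:
    path = Path(path)
    doc = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "background_activity": spec.background_activity,
        "lesion_to_background": spec.lesion_to_background,
        "seed": spec.seed,
        "lesions": [{
            "center_mm": list(l.center_mm), "diameter_mm": l.diameter_mm,
            "activity_kbq_ml": l.activity_kbq_ml, "hu": l.hu, "mu": l.mu,
        } for l in spec.lesions],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
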