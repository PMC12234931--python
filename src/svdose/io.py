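"""NIfTI image/mask I/O and run configuration.

Images and masks travel as NIfTI-1 with a diagonal affine carrying the
voxel spacing (mm) and the grid origin; intensity units are recorded in
a JSON sidecar next to the image.  Real patient data enters the
pipeline the same way: an image + mask pair per kidney and a CSV of
sample times.  Run configurations round-trip through YAML and are
identified by a content hash, which every artifact directory records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import MaskVOI, VoxelImage

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "RunConfig",
    "config_hash",
]

_OFFDIAG_TOL = 1e-4


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(path: Path, affine: np.ndarray):
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: missing or non-finite affine")
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > _OFFDIAG_TOL:
        raise ValueError(
            f"{path}: oblique/sheared affine is ambiguous for this pipeline; "
            "expected a diagonal voxel-to-world matrix"
        )
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine implies non-positive voxel spacing")
    return tuple(spacing), tuple(affine[:3, 3])


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_image(image: VoxelImage, path) -> Path:
    """Write a :class:`VoxelImage` as NIfTI + a units sidecar JSON."""
    path = Path(path)
    nii = nib.Nifti1Image(
        image.values.astype(np.float32), _affine_from(image.spacing, image.origin)
    )
    nib.save(nii, path)
    _sidecar(path).write_text(json.dumps({"units": image.units}, indent=2))
    return path


def read_image(path) -> VoxelImage:
    """Read a NIfTI image; spacing/origin come from the affine."""
    path = Path(path)
    try:
        nii = nib.load(path)
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    spacing, origin = _grid_from_affine(path, nii.affine)
    units = "dimensionless"
    sidecar = _sidecar(path)
    if sidecar.exists():
        units = json.loads(sidecar.read_text()).get("units", units)
    values = np.asarray(nii.get_fdata(), dtype=float)
    return VoxelImage(values=values, spacing=spacing, origin=origin, units=units)


def write_mask(mask: MaskVOI, path) -> Path:
    """Write a weighted mask as NIfTI (values in [0, 1])."""
    path = Path(path)
    nii = nib.Nifti1Image(
        mask.weights.astype(np.float32), _affine_from(mask.spacing, mask.origin)
    )
    nib.save(nii, path)
    _sidecar(path).write_text(
        json.dumps(
            {"label": mask.label, "nominal_volume_ml": mask.nominal_volume_ml},
            indent=2,
        )
    )
    return path


def read_mask(path) -> MaskVOI:
    """Read a mask NIfTI; binary masks load as 0/1 weights."""
    path = Path(path)
    try:
        nii = nib.load(path)
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    spacing, origin = _grid_from_affine(path, nii.affine)
    weights = np.asarray(nii.get_fdata(), dtype=float)
    if weights.min() < -1e-4 or weights.max() > 1 + 1e-4:
        raise ValueError(
            f"{path}: mask values outside [0, 1] "
            f"(range {weights.min():.4g}..{weights.max():.4g})"
        )
    label, nominal = "", None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", "")
        nominal = meta.get("nominal_volume_ml")
    return MaskVOI(
        weights=np.clip(weights, 0.0, 1.0), spacing=spacing, origin=origin,
        label=label, nominal_volume_ml=nominal,
    )


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serialisable to YAML."""

    n_patients: int = 18
    seed: int = 0
    preset: str = "ASCC"
    sigmas_mm: tuple = (0.0, 4.0)
    sv_volumes_ml: tuple = (4.0, 2.0, 0.6)
    n_svs_max: int = 5
    times_h: tuple = (24.0, 48.0, 168.0)
    noise: bool = True
    volume_range_ml: tuple = (31.0, 243.0)
    thickness_range_mm: tuple = (12.0, 22.0)
    texture_cv: float = 0.10
    background_fraction: float = 0.05
    spacing_mm: float = 4.42
    admin_activity_gbq: float = 7.4

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(getattr(cls, f.name, None), tuple):
                data[f.name] = tuple(data[f.name])
        for name in ("sigmas_mm", "sv_volumes_ml", "times_h",
                     "volume_range_ml", "thickness_range_mm"):
            if name in data and isinstance(data[name], list):
                data[name] = tuple(data[name])
        return cls(**data)

    def hash(self) -> str:
        return config_hash(self)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable content hash identifying a run configuration."""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]
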