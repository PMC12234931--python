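"""Voxel grids and weighted volumes of interest.

All world coordinates are millimetres; voxel indices are 0-based and
ordered (x, y, z) to match the array axes.  Volumes are reported in mL
(1 mL = 1000 mm^3).  A :class:`MaskVOI` carries fractional voxel
membership in [0, 1], so sub-voxel structures (thin parenchyma rims,
small spheres) are represented without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelImage", "MaskVOI", "check_aligned", "GridAlignmentError"]

MM3_PER_ML = 1000.0


class GridAlignmentError(ValueError):
    """Raised when an image and a VOI do not share the same grid."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"spacing must be positive and finite, got {spacing!r}")
    return tuple(arr)


@dataclass
class VoxelImage:
    """A 3-D scalar field on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples.  The physical meaning is declared in ``units``
        (e.g. ``"MBq/mL"`` for activity concentration, ``"cps/voxel"``
        for emulated count-rate images).
    spacing : float or 3-sequence
        Voxel edge lengths in mm.
    origin : 3-sequence, optional
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if min(self.values.shape) < 8:
            raise ValueError(
                f"grid dimensions must be >= 8 per axis, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / MM3_PER_ML

    def with_values(self, values: np.ndarray, units: str | None = None) -> "VoxelImage":
        """A new image on the same grid with different values."""
        return VoxelImage(
            values=np.asarray(values, dtype=float),
            spacing=self.spacing,
            origin=self.origin,
            units=self.units if units is None else units,
        )

    def voxel_centers(self):
        """World coordinates (mm) of voxel centres as three 1-D axes."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def total(self) -> float:
        """Sum of all voxel values (e.g. total cps for a count image)."""
        return float(self.values.sum())


@dataclass
class MaskVOI:
    """Fractional voxel membership aligned to a :class:`VoxelImage` grid.

    ``weights`` live on the same grid as the image the VOI is used with;
    grid identity is enforced at evaluation time (no resampling).
    """

    weights: np.ndarray
    spacing: tuple[float, float, float]
    label: str = ""
    nominal_volume_ml: float | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be a 3-D array")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("mask weights must lie in [0, 1]")
        self.weights = np.clip(self.weights, 0.0, 1.0)
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.weights.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / MM3_PER_ML

    @property
    def volume_ml(self) -> float:
        """Weighted volume: sum of weights times the voxel volume."""
        return float(self.weights.sum()) * self.voxel_volume_ml

    def is_empty(self) -> bool:
        return not np.any(self.weights > 0)


def check_aligned(image: VoxelImage, voi: MaskVOI) -> None:
    """Require identical grid shape, spacing and origin (no resampling)."""
    if image.shape != voi.shape:
        raise GridAlignmentError(
            f"shape mismatch: image {image.shape} vs mask {voi.shape}"
        )
    if not np.allclose(image.spacing, voi.spacing, rtol=0, atol=1e-9):
        raise GridAlignmentError(
            f"spacing mismatch: image {image.spacing} vs mask {voi.spacing}"
        )
    if not np.allclose(image.origin, voi.origin, rtol=0, atol=1e-6):
        raise GridAlignmentError(
            f"origin mismatch: image {image.origin} vs mask {voi.origin}"
        )
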