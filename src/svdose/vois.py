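"""Spherical small VOIs, count summation and representative placement.

The clinical small-VOI (SV) method samples the kidney parenchyma with a
few spheres (4, 2 or 0.6 mL) placed in regions judged representative of
the mean activity concentration — toward the pelvis, away from the
outer cortex edge, avoiding hot and cold spots.  Here that visual
judgement is replaced by a deterministic algorithm: candidate centres
are restricted to the inner half of the parenchyma (by distance to
background), scored by how far the sphere-averaged concentration at the
centre deviates from the parenchyma median, and selected greedily under
a minimum-separation constraint.  Spheres are deliberately *not*
clipped to the parenchyma: like the clinical procedure, all counts in
the sphere contribute, which is what produces the small-VOI bias when
the sphere outgrows the parenchyma rim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import MM3_PER_ML, MaskVOI, VoxelImage, check_aligned
from .phantoms import _ellipsoid_indicator, _fractional_weights

__all__ = ["SVSet", "sphere_voi", "voi_counts", "place_svs", "wkp_from_mask",
           "sphere_diameter_mm"]

DEFAULT_SV_VOLUMES_ML = (4.0, 2.0, 0.6)
_SUPERSAMPLE = 9


def sphere_diameter_mm(volume_ml: float) -> float:
    """Diameter of a sphere of the given volume: d = 2 (3V / 4 pi)^(1/3)."""
    return 2.0 * (3.0 * volume_ml * MM3_PER_ML / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class SVSet:
    """An ordered set of spherical small VOIs on one image grid."""

    centers_mm: list[tuple[float, float, float]]
    sv_volume_ml: float
    masks: list[MaskVOI]
    scores: list[float] = field(default_factory=list)
    incomplete: bool = False  # fewer centres than requested were feasible

    def __len__(self) -> int:
        return len(self.masks)


def sphere_voi(center_mm, volume_ml: float, grid: VoxelImage) -> MaskVOI:
    """Partial-volume-weighted sphere mask on the grid of ``grid``.

    Weights come from supersampled voxelisation (9 sub-samples per axis), evaluated only on
    the sphere's bounding box for speed.
    """
    center = np.asarray(center_mm, dtype=float)
    radius = sphere_diameter_mm(volume_ml) / 2.0
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    upper = origin + spacing * (shape - 1)
    if np.any(center < origin - spacing / 2) or np.any(center > upper + spacing / 2):
        raise ValueError(f"sphere centre {tuple(center)} lies outside the image grid")

    lo = np.maximum(0, np.floor((center - radius - origin) / spacing).astype(int) - 1)
    hi = np.minimum(shape, np.ceil((center + radius - origin) / spacing).astype(int) + 2)
    sub_shape = tuple(int(n) for n in (hi - lo))
    sub_origin = tuple(origin + spacing * lo)
    sub = _fractional_weights(
        _ellipsoid_indicator((radius, radius, radius), center=tuple(center)),
        sub_shape,
        tuple(spacing),
        sub_origin,
        _SUPERSAMPLE,
    )
    weights = np.zeros(grid.shape)
    weights[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return MaskVOI(
        weights=weights,
        spacing=grid.spacing,
        origin=grid.origin,
        label=f"SV{volume_ml:g}",
        nominal_volume_ml=volume_ml,
    )


def voi_counts(image: VoxelImage, voi: MaskVOI) -> float:
    """Weighted sum of voxel values over the VOI (cps for count images)."""
    check_aligned(image, voi)
    return float(np.sum(image.values * voi.weights))


def _sphere_kernel(volume_ml: float, spacing) -> np.ndarray:
    """Normalised sphere-averaging kernel centred on a voxel centre."""
    radius = sphere_diameter_mm(volume_ml) / 2.0
    spacing = np.asarray(spacing, dtype=float)
    half = np.ceil(radius / spacing).astype(int) + 1
    shape = tuple(2 * half + 1)
    origin = tuple(-spacing * half)
    k = _fractional_weights(
        _ellipsoid_indicator((radius, radius, radius)), shape, tuple(spacing), origin,
        _SUPERSAMPLE,
    )
    return k / k.sum()


def place_svs(
    image: VoxelImage,
    wkp: MaskVOI,
    sv_volume_ml: float,
    k: int = 5,
    *,
    min_sep_mm: float | None = None,
    inner_fraction: float = 0.5,
) -> SVSet:
    """Deterministically place up to ``k`` representative spheres.

    1. Candidate centres are parenchyma voxels whose distance to the
       background is at least ``inner_fraction`` of the kidney's maximum
       (the "toward the pelvis, away from the outer cortex" rule).
    2. Each candidate is scored by |sphere mean at the centre - WKP
       median| computed by sphere-kernel convolution of the image.
    3. Centres are selected greedily in ascending (score, linear index)
       order subject to a pairwise separation of at least
       ``max(sphere diameter, min_sep_mm)``.

    Identical inputs give identical placements, and the selection is
    nested: requesting k+1 spheres never changes the first k.  If fewer
    than ``k`` centres are feasible, all feasible ones are returned with
    ``incomplete=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    check_aligned(image, wkp)
    if wkp.is_empty():
        raise ValueError("WKP mask is empty")

    binary = wkp.weights >= 0.5
    if not np.any(binary):
        binary = wkp.weights > 0
    dist = ndimage.distance_transform_edt(binary, sampling=wkp.spacing)
    inner = binary & (dist >= inner_fraction * dist.max())

    kernel = _sphere_kernel(sv_volume_ml, image.spacing)
    sphere_mean = ndimage.convolve(image.values, kernel, mode="constant", cval=0.0)
    target = float(np.median(image.values[binary]))
    score = np.abs(sphere_mean - target)

    idx = np.flatnonzero(inner.ravel())
    order = np.lexsort((idx, score.ravel()[idx]))
    candidates = idx[order]

    diameter = sphere_diameter_mm(sv_volume_ml)
    sep = max(diameter, min_sep_mm) if min_sep_mm is not None else diameter
    origin = np.asarray(image.origin)
    spacing = np.asarray(image.spacing)

    chosen: list[np.ndarray] = []
    chosen_scores: list[float] = []
    for flat in candidates:
        if len(chosen) == k:
            break
        coord = origin + spacing * np.array(np.unravel_index(flat, image.shape))
        if all(np.linalg.norm(coord - c) >= sep for c in chosen):
            chosen.append(coord)
            chosen_scores.append(float(score.ravel()[flat]))

    masks = [sphere_voi(tuple(c), sv_volume_ml, image) for c in chosen]
    return SVSet(
        centers_mm=[tuple(float(x) for x in c) for c in chosen],
        sv_volume_ml=sv_volume_ml,
        masks=masks,
        scores=chosen_scores,
        incomplete=len(chosen) < k,
    )


def wkp_from_mask(mask: MaskVOI) -> tuple[float, MaskVOI]:
    """Volume (mL) of a parenchyma mask, as used for the reference method."""
    if mask.is_empty():
        raise ValueError("mask is empty")
    return mask.volume_ml, mask
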