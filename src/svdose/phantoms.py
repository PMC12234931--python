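"""Digital phantoms with known activity ground truth.

Kidney parenchyma (cortex + medulla, excluding the renal pelvis) is
modelled as an axis-aligned outer ellipsoid minus an interior cavity
ellipsoid whose semi-axes are shortened by the parenchyma thickness, so
the shell has exactly the requested thickness along each principal axis.
This two-parameter (volume, thickness) family captures the thin-rim
geometry that makes small spherical VOIs sample the parenchyma
imperfectly, which is the effect the package studies.

Activity is uniform inside the parenchyma (optionally modulated by a
voxel-wise lognormal texture), washes out mono-exponentially per kidney,
and a configurable low-level background can be added in a surrounding
"body" region.  Masks are voxelised with supersampling so boundary
voxels carry fractional weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .grids import MM3_PER_ML, MaskVOI, VoxelImage

__all__ = [
    "GeometryError",
    "CohortSpec",
    "KidneyPhantom",
    "make_kidney_phantom",
    "make_sphere_phantom",
    "make_calibration_phantom",
    "make_cohort",
    "activity_at",
    "max_feasible_thickness",
    "reference_shell_cohort",
    "KIDNEY_DENSITY_G_PER_ML",
]

# Parenchyma density used to convert MBq/g <-> MBq/mL.
KIDNEY_DENSITY_G_PER_ML = 1.05

# Fixed kidney ellipsoid aspect ratio (long axis : width : depth).
_AXIS_RATIOS = np.array([1.6, 1.0, 0.85])

# Body region (background compartment) relative to the outer ellipsoid.
_BODY_SCALE = 1.35


class GeometryError(ValueError):
    """An infeasible phantom geometry request."""


def _make_grid(half_extent_mm, spacing, margin_mm):
    """Grid shape/origin centred on the phantom with a zero-activity margin.

    The margin keeps blurred counts inside the array so acquisition
    conserves total counts.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    half = np.asarray(half_extent_mm, dtype=float) + margin_mm
    n = np.maximum(8, 2 * np.ceil(half / spacing).astype(int) + 1)
    origin = -spacing * (n - 1) / 2.0
    return tuple(n), tuple(spacing), tuple(origin)


def _fractional_weights(predicate, shape, spacing, origin, factor):
    """Supersampled voxelisation: fraction of each voxel inside ``predicate``.

    ``predicate`` is a vectorised function of world coordinates (mm)
    returning values in [0, 1] (typically a boolean indicator).  Each
    voxel is subdivided ``factor`` times per axis and the indicator is
    averaged over the sub-voxel centres.
    """
    axes = []
    for i in range(3):
        n, d, o = shape[i], spacing[i], origin[i]
        sub = (np.arange(factor) + 0.5) / factor - 0.5  # offsets in voxel units
        fine = (o + d * (np.arange(n)[:, None] + sub[None, :])).reshape(-1)
        axes.append(fine)
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    ind = np.asarray(predicate(x, y, z), dtype=float)
    f = factor
    ind = ind.reshape(shape[0], f, shape[1], f, shape[2], f)
    return ind.mean(axis=(1, 3, 5))


def _ellipsoid_indicator(semiaxes, center=(0.0, 0.0, 0.0)):
    a, b, c = semiaxes
    cx, cy, cz = center

    def predicate(x, y, z):
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0

    return predicate


def _shell_volume_mm3(scale: float, thickness: float) -> float:
    outer = _AXIS_RATIOS * scale
    inner = np.maximum(outer - thickness, 0.0)
    return 4.0 / 3.0 * math.pi * (np.prod(outer) - np.prod(inner))


def _solve_shell_scale(volume_ml: float, thickness: float) -> float:
    """Ellipsoid scale such that the shell volume equals ``volume_ml``."""
    target = volume_ml * MM3_PER_ML
    # Scale at which the cavity just opens; below it the shape is solid
    # and the requested thickness cannot be realised.
    s_open = thickness / _AXIS_RATIOS.min()
    v_open = 4.0 / 3.0 * math.pi * np.prod(_AXIS_RATIOS) * s_open**3
    if target <= v_open:
        raise GeometryError(
            f"volume {volume_ml:.1f} mL is too small for a parenchyma shell of "
            f"thickness {thickness:.1f} mm (needs > {v_open / MM3_PER_ML:.1f} mL); "
            f"reduce the thickness (max {max_feasible_thickness(volume_ml):.1f} mm)"
        )
    s_hi = s_open
    while _shell_volume_mm3(s_hi, thickness) < target:
        s_hi *= 2.0
    return brentq(
        lambda s: _shell_volume_mm3(s, thickness) - target, s_open, s_hi, xtol=1e-10
    )


def max_feasible_thickness(volume_ml: float) -> float:
    """Largest parenchyma thickness (mm) realisable for a given volume."""
    s_solid = (3.0 * volume_ml * MM3_PER_ML / (4.0 * math.pi * np.prod(_AXIS_RATIOS))) ** (
        1.0 / 3.0
    )
    return float(_AXIS_RATIOS.min() * s_solid)


@dataclass
class KidneyPhantom:
    """Ground-truth kidney geometry and kinetics.

    ``truth_image`` holds the activity concentration (MBq/mL) at the
    reference time t = 0; ``C0`` is the matching concentration in MBq/g
    (``truth = C0 * density`` inside the parenchyma, before texture).
    Washout is mono-exponential with rate ``lam`` (1/h).
    """

    truth_image: VoxelImage
    wkp_mask: MaskVOI
    parenchyma_thickness_mm: float
    C0: float  # MBq/g at t = 0
    lam: float  # 1/h
    kidney_id: str = "kidney"
    admin_activity_gbq: float = 7.4

    def __post_init__(self) -> None:
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def volume_ml(self) -> float:
        return self.wkp_mask.volume_ml

    def true_dose_gy(self) -> float:
        """Analytic absorbed dose for the generating kinetics (local
        energy deposit), ignoring texture: (C0 / lambda) * K."""
        from .dosimetry import DOSE_PER_TIAC_GY

        return self.C0 / self.lam * DOSE_PER_TIAC_GY


def make_kidney_phantom(
    volume_ml: float,
    thickness_mm: float,
    spacing: float | tuple = 4.42,
    C0: float = 0.6,
    lam: float = math.log(2) / 50.0,
    *,
    texture_cv: float = 0.0,
    background_fraction: float = 0.0,
    margin_mm: float = 45.0,
    supersample: int = 3,
    seed: int | None = None,
    kidney_id: str = "kidney",
    admin_activity_gbq: float = 7.4,
) -> KidneyPhantom:
    """Build an ellipsoid-shell kidney phantom with uniform uptake.

    Parameters
    ----------
    volume_ml : float
        Target parenchyma volume, 20-300 mL; the voxelised mask matches
        it within 2%.
    thickness_mm : float
        Parenchyma shell thickness (8-30 mm), realised exactly along the
        principal axes.
    spacing : float
        Isotropic grid spacing in mm (default 4.42, the SPECT grid).
    C0, lam : float
        Reference activity concentration (MBq/g) and washout rate (1/h).
    texture_cv : float
        Coefficient of variation of an optional voxel-wise lognormal
        multiplier (mean 1) emulating non-uniform uptake; 0 = uniform.
    background_fraction : float
        Background concentration in the surrounding body region (and the
        pelvis cavity) as a fraction of the parenchyma concentration.
    margin_mm : float
        Zero-activity margin so blurred counts stay on the grid.
    """
    if not (20.0 <= volume_ml <= 300.0):
        raise GeometryError(f"volume must be in [20, 300] mL, got {volume_ml}")
    if not (8.0 <= thickness_mm <= 30.0):
        raise GeometryError(f"thickness must be in [8, 30] mm, got {thickness_mm}")
    spacing3 = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if np.any(spacing3 > thickness_mm):
        raise GeometryError(
            f"spacing {tuple(spacing3)} must not exceed the parenchyma thickness "
            f"{thickness_mm} mm"
        )
    if not (0.0 <= background_fraction <= 0.5):
        raise ValueError("background_fraction must be in [0, 0.5]")

    scale = _solve_shell_scale(volume_ml, thickness_mm)
    outer = _AXIS_RATIOS * scale
    inner = np.maximum(outer - thickness_mm, 0.0)

    shape, spc, origin = _make_grid(outer, spacing3, margin_mm)
    frac_outer = _fractional_weights(
        _ellipsoid_indicator(outer), shape, spc, origin, supersample
    )
    frac_inner = (
        _fractional_weights(_ellipsoid_indicator(inner), shape, spc, origin, supersample)
        if np.all(inner > 0)
        else 0.0
    )
    weights = np.clip(frac_outer - frac_inner, 0.0, 1.0)

    mask = MaskVOI(
        weights=weights,
        spacing=spc,
        origin=origin,
        label=f"WKP:{kidney_id}",
        nominal_volume_ml=volume_ml,
    )

    conc = C0 * KIDNEY_DENSITY_G_PER_ML  # MBq/mL in the parenchyma
    values = conc * weights
    if texture_cv > 0:
        rng = np.random.default_rng(seed)
        sigma_ln = math.sqrt(math.log(1.0 + texture_cv**2))
        texture = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=shape)
        values = conc * weights * texture
    if background_fraction > 0:
        body = _fractional_weights(
            _ellipsoid_indicator(outer * _BODY_SCALE), shape, spc, origin, supersample
        )
        values = values + background_fraction * conc * np.clip(body - weights, 0.0, 1.0)

    truth = VoxelImage(values=values, spacing=spc, origin=origin, units="MBq/mL")
    return KidneyPhantom(
        truth_image=truth,
        wkp_mask=mask,
        parenchyma_thickness_mm=thickness_mm,
        C0=C0,
        lam=lam,
        kidney_id=kidney_id,
        admin_activity_gbq=admin_activity_gbq,
    )


def make_sphere_phantom(
    volume_ml: float,
    spacing: float | tuple = 4.42,
    *,
    C0: float = 0.6,
    lam: float = math.log(2) / 50.0,
    margin_mm: float = 45.0,
    supersample: int | None = None,
    kidney_id: str = "sphere",
) -> KidneyPhantom:
    """Uniform sphere phantom (the classical recovery-curve geometry).

    ``supersample`` defaults to a factor giving sub-samples of about
    0.5 mm, which keeps the voxelised volume within 0.5% of nominal.
    """
    spacing3 = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    if supersample is None:
        supersample = max(3, int(np.ceil(float(spacing3.max()) / 0.5)))
    voxel_ml = float(np.prod(spacing3)) / MM3_PER_ML
    if volume_ml <= voxel_ml:
        raise GeometryError(
            f"sphere of {volume_ml} mL is smaller than one voxel ({voxel_ml:.3f} mL)"
        )
    radius = (3.0 * volume_ml * MM3_PER_ML / (4.0 * math.pi)) ** (1.0 / 3.0)
    shape, spc, origin = _make_grid(np.full(3, radius), spacing3, margin_mm)
    weights = _fractional_weights(
        _ellipsoid_indicator((radius, radius, radius)), shape, spc, origin, supersample
    )
    mask = MaskVOI(
        weights=weights,
        spacing=spc,
        origin=origin,
        label=f"sphere:{volume_ml}mL",
        nominal_volume_ml=volume_ml,
    )
    conc = C0 * KIDNEY_DENSITY_G_PER_ML
    truth = VoxelImage(values=conc * weights, spacing=spc, origin=origin, units="MBq/mL")
    return KidneyPhantom(
        truth_image=truth,
        wkp_mask=mask,
        parenchyma_thickness_mm=2 * radius,
        C0=C0,
        lam=lam,
        kidney_id=kidney_id,
    )


def make_calibration_phantom(
    activity_mbq: float,
    volume_ml: float = 6000.0,
    spacing: float | tuple = 4.42,
    *,
    voi_margin_mm: float = 25.0,
    margin_mm: float = 45.0,
    supersample: int = 3,
) -> tuple[VoxelImage, MaskVOI]:
    """Uniform cylinder of known activity plus an interior measurement VOI.

    Emulates a uniformly filled calibration (Jaszczak-style) cylinder;
    the VOI is eroded from the cylinder wall by ``voi_margin_mm`` so the
    spill-out it loses is compensated by spill-in from the surrounding
    uniform activity, which is what makes the count-per-activity factor
    Q measurable without a recovery correction.
    """
    if activity_mbq < 0:
        raise ValueError("activity must be non-negative")
    spacing3 = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    # Cylinder with height equal to its diameter: V = 2 * pi * r^3.
    radius = (volume_ml * MM3_PER_ML / (2.0 * math.pi)) ** (1.0 / 3.0)
    height = 2.0 * radius
    if radius <= voi_margin_mm:
        raise GeometryError(
            f"cylinder radius {radius:.1f} mm leaves no room for a VOI margin of "
            f"{voi_margin_mm} mm"
        )

    def cylinder(r, h):
        def predicate(x, y, z):
            return (x**2 + y**2 <= r**2) & (np.abs(z) <= h / 2.0)

        return predicate

    shape, spc, origin = _make_grid(
        (radius, radius, height / 2.0), spacing3, margin_mm
    )
    weights = _fractional_weights(cylinder(radius, height), shape, spc, origin, supersample)
    measured_volume = float(weights.sum()) * float(np.prod(spc)) / MM3_PER_ML
    conc = activity_mbq / measured_volume  # MBq/mL, exact total by construction
    truth = VoxelImage(values=conc * weights, spacing=spc, origin=origin, units="MBq/mL")

    voi_weights = _fractional_weights(
        cylinder(radius - voi_margin_mm, height - 2.0 * voi_margin_mm),
        shape,
        spc,
        origin,
        supersample,
    )
    voi = MaskVOI(
        weights=voi_weights,
        spacing=spc,
        origin=origin,
        label="calibration-VOI",
        nominal_volume_ml=None,
    )
    return truth, voi


@dataclass
class CohortSpec:
    """Sampling distributions for a synthetic patient cohort.

    Defaults emulate the study conditions: 18 patients (36 kidneys),
    parenchyma volumes 31-243 mL, thickness 12-22 mm on a 4.42 mm grid,
    effective half-lives 30-70 h, lognormal reference concentrations
    around 0.6 MBq/g, 10% uptake texture and 5% body background.
    """

    n_patients: int = 18
    volume_range_ml: tuple[float, float] = (31.0, 243.0)
    thickness_range_mm: tuple[float, float] = (12.0, 22.0)
    C0_distribution: tuple[float, float] = (math.log(0.6), 0.4)  # (log-mean, log-sd)
    half_life_range_h: tuple[float, float] = (30.0, 70.0)
    background_fraction: float = 0.05
    texture_cv: float = 0.10
    spacing_mm: float = 4.42
    margin_mm: float = 45.0
    admin_activity_gbq: float = 7.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("volume_range_ml", "thickness_range_mm", "half_life_range_h"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not (0.0 <= self.background_fraction <= 0.5):
            raise ValueError("background_fraction must be in [0, 0.5]")
        if self.texture_cv < 0:
            raise ValueError("texture_cv must be non-negative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def make_cohort(spec: CohortSpec) -> list[KidneyPhantom]:
    """Draw a deterministic cohort of 2 kidneys per patient.

    The thickness draw is clipped to the feasible range for the drawn
    volume (small kidneys cannot carry an arbitrarily thick shell), so
    small parenchyma volumes come with thin rims, as they do clinically.
    """
    rng = np.random.default_rng(spec.seed)
    phantoms: list[KidneyPhantom] = []
    log_mu, log_sd = spec.C0_distribution
    for p in range(spec.n_patients):
        for side in ("L", "R"):
            volume = rng.uniform(*spec.volume_range_ml)
            t_hi = min(spec.thickness_range_mm[1], 0.95 * max_feasible_thickness(volume))
            t_lo = min(spec.thickness_range_mm[0], t_hi)
            thickness = rng.uniform(t_lo, t_hi)
            c0 = float(rng.lognormal(mean=log_mu, sigma=log_sd))
            half_life = rng.uniform(*spec.half_life_range_h)
            texture_seed = int(rng.integers(0, 2**31 - 1))
            phantoms.append(
                make_kidney_phantom(
                    volume_ml=volume,
                    thickness_mm=thickness,
                    spacing=spec.spacing_mm,
                    C0=c0,
                    lam=math.log(2) / half_life,
                    texture_cv=spec.texture_cv,
                    background_fraction=spec.background_fraction,
                    margin_mm=spec.margin_mm,
                    seed=texture_seed,
                    kidney_id=f"P{p + 1:02d}{side}",
                    admin_activity_gbq=spec.admin_activity_gbq,
                )
            )
    return phantoms


def activity_at(phantom: KidneyPhantom, t_h: float) -> VoxelImage:
    """Activity concentration image at time ``t_h`` hours post reference."""
    if t_h < 0:
        raise ValueError("time must be non-negative")
    decayed = phantom.truth_image.values * math.exp(-phantom.lam * t_h)
    return phantom.truth_image.with_values(decayed)


# Fixed reference cohort used to calibrate the acquisition presets and to
# characterise recovery over the study's volume/thickness range.  Uniform
# uptake and no background: recovery is a purely geometric quantity here.
_REFERENCE_SEED = 20250708 % (2**31 - 1)


def reference_shell_cohort(spacing: float = 4.42) -> list[KidneyPhantom]:
    """36 uniform shell kidneys spanning 31-243 mL / 12-22 mm thickness."""
    spec = CohortSpec(
        n_patients=18,
        volume_range_ml=(31.0, 243.0),
        thickness_range_mm=(12.0, 22.0),
        texture_cv=0.0,
        background_fraction=0.0,
        spacing_mm=spacing,
        seed=_REFERENCE_SEED,
    )
    return make_cohort(spec)
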