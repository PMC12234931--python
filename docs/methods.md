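# Methods

This note records the models behind `svdose`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic experiments
can and cannot say about patient data.

## Kidney phantoms

The parenchyma is an axis-aligned outer ellipsoid minus an interior
cavity ellipsoid whose semi-axes are shortened by the parenchyma
thickness.  The aspect ratio is fixed at 1.6 : 1 : 0.85 (long axis :
width : depth, roughly a human kidney); the single free scale is solved
by `brentq` so the analytic shell volume matches the request, which the
voxelised mask then reproduces within 2%.  Thickness is exact along the
principal axes.  A (volume, thickness) pair is infeasible when the
requested shell would have to be solid — the feasibility bound is
`max_feasible_thickness(volume)` — and cohort sampling truncates the
thickness draw accordingly, so small kidneys come with thin rims, as
they do clinically.

Masks carry fractional voxel weights from supersampled voxelisation
(3 sub-samples per axis for organ-scale shells; spheres use a factor
giving ≈0.5 mm sub-samples so their weighted volume stays within 0.5%
of nominal).  The grid default is 4.42 mm isotropic, the voxel size of
the emulated SPECT protocol, with a 45 mm zero-activity margin so
blurring conserves counts on-grid.

Kinetics are per-kidney mono-exponential, C(t) = C₀·e^(−λt), so the
dose model's fit is exact on noiseless phantoms and any end-to-end error
isolates the imaging chain.  Cohort defaults (18 patients, 2 kidneys
each): volumes uniform on 31–243 mL; thickness uniform on 12–22 mm
(feasibility-truncated); C₀ lognormal with median 0.6 MBq/g and log-SD
0.4, which puts kidney doses near the clinically typical ~0.5 Gy/GBq;
effective half-lives uniform on 30–70 h, bracketing reported kidney
clearance of ¹⁷⁷Lu-DOTATATE; administered activity 7.4 GBq.  Optional
voxel-wise lognormal uptake texture (default CV 0.10) and a body
background at 5% of the parenchyma concentration (inside a 1.35×
enlarged ellipsoid, including the pelvis cavity) emulate non-uniform
uptake and surrounding tissue; oracle tests use the uniform,
background-free mode.

## Acquisition emulator

Projection, scatter and iterative reconstruction are replaced by their
net image-domain effect: activity per voxel is convolved with a
stationary isotropic Gaussian PSF, scaled by a sensitivity Q (default
10 cps/MBq, a typical medium-energy-collimator value for ¹⁷⁷Lu),
optionally Poisson-sampled at the count level over the acquisition time
(default 3600 s = 120 projections × 30 s), and optionally post-filtered
with a second Gaussian (σ up to 12 mm).

The blur is a sampled-Gaussian spatial convolution
(`scipy.ndimage.gaussian_filter`, zero-padded, truncation radius 8σ).
This choice guarantees non-negative images (required before Poisson
sampling), exact linearity, count conservation given the phantom
margin, and filter composition in quadrature (σ₁ then σ₂ ≈ √(σ₁²+σ₂²))
to well below 1e-6 for filter widths at or above the grid spacing.  An
exact Fourier-domain Gaussian was rejected: below one voxel width it
rings negative at sharp edges.

The `ASCC` preset (high resolution, fully corrected reconstruction) has
its system σ calibrated once — stored in `data/presets.yaml`,
regenerated by `scripts/calibrate_preset.py` — so that the mean
whole-parenchyma recovery coefficient over a fixed 36-kidney reference
shell cohort equals 0.85, the guideline-level recovery used for
parenchyma dosimetry with such protocols; the calibrated value is
σ = 2.374 mm.  The `AC` preset (attenuation-only, heavily smoothed) is
defined as the ASCC response plus 6 mm of Gaussian smoothing in
quadrature, the filter width at which the two recovery curves coincide;
on the reference cohort it yields a mean RC of 0.66 with no separate
tuning.  The PSF is stationary and isotropic — no distance-dependent
resolution, no iteration-count effects, no Gibbs overshoot (see
Limitations).

## VOI measurement conventions

All VOI counts are fractional-weight sums: `voi_counts` multiplies the
image by the mask weights.  Recovery simulation uses the *same*
convention on the *same* mask that defines the phantom truth, which
makes the reference dose chain exactly self-consistent: on a noiseless
uniform phantom the RC-corrected WKP concentration equals the true
concentration identically, so end-to-end dose error measures only what
the experiment adds (noise, texture, curve-predicted RC).

A consequence worth stating: for a mask with partial-weight boundary
voxels the recovery coefficient at zero blur is Σw²/Σw < 1 — the
tissue-fraction effect of measuring a sub-voxel structure on the
acquisition grid (≈0.91 for the reference shells).  RC = 1 at zero blur
holds exactly for binary masks.  This is deliberate: a CT-derived
parenchyma contour measured on the SPECT grid includes the same effect,
and the simulated RC is meant to absorb it.

Sphere VOIs are *not* clipped to the parenchyma: all counts inside the
sphere contribute and the concentration divides by the sphere's
realised (weighted) volume.  That reproduces the clinical procedure and
is the mechanism of the small-VOI bias when the sphere out-grows the
rim.

## Representative sphere placement

Visual placement ("representative of the mean concentration, toward the
pelvis, away from the outer cortex, avoiding hot and cold spots") is
operationalised deterministically:

1. candidate centres are parenchyma voxels whose distance to background
   is at least half the kidney's maximum (the inner half of the rim);
2. each candidate is scored by |sphere-mean at that centre − parenchyma
   median| via sphere-kernel convolution (the median is robust to
   hotspots, hence "avoiding" them);
3. centres are chosen greedily by ascending (score, linear voxel index)
   subject to a pairwise separation of one sphere diameter (default;
   configurable), so placements are reproducible, hotspot-averse and
   nested — the first k spheres do not change when k+1 are requested.

If fewer than k centres satisfy the separation constraint (20 mm
spheres in the smallest kidneys), all feasible ones are returned with a
warning flag.  The "inner half" fraction and the separation are exposed
parameters, not claims about how clinicians place spheres.

## Dose calculation

Physical constants are centralised in `dosimetry`: 1 MBq·h = 3.6e9
decays, 147 keV mean electron energy per decay, 1 keV = 1.602177e-16 J,
ρ = 1.05 g/mL, giving D = TIAC × 0.08479 Gy/(MBq·h/g) under local
energy deposit (no electron transport, no photon self- or cross-dose).
The washout fit is a log-linear least squares (exact on noiseless
mono-exponential data) refined by nonlinear least squares on the linear
scale; `method="loglinear"` skips the refinement.  Fitted rates at or
below 1e-6/h are rejected as non-decaying rather than extrapolated to
infinite TIAC.  The time integral runs from zero — no uptake phase is
modelled, consistent with sampling from 24 h onward.  The default
WKP recovery source is the per-kidney simulated RC; the fitted RC(V)
curve is an alternative (`rc_source="curve"`), accurate to ~4% on the
reference cohort.

## Agreement statistics and the sweep

The normalization factor is the arithmetic mean of single-sphere dose
ratios D_SV/D_WKP, estimated separately per (sphere volume, filter σ)
stratum — never pooled across filters, since it tracks resolution — and
applied as D_SVN = D_SV/NF.  Bias and accuracy are the sample mean and
SD (n−1) of PD = 100·(D_SVN − D_WKP)/D_WKP; Bland-Altman limits are
bias ± 1.96 SD on the same scale.  In-sample, NF correction zeroes the
mean PD algebraically; an optional train/test split quantifies the
optimism of that identity on held-out kidneys.  `run_sweep` evaluates
every (sphere volume, sphere count 1–5, filter σ) cell on a cohort,
using the first k of 5 placed spheres (prefix means) and averaging SV
concentrations per time point before fitting.

Problem sizes: the shipped experiments use the 36-kidney default cohort,
three time points (24/48/168 h), filters σ ∈ {0, 4} mm and both presets;
the whole test suite plus the reproduction script completes in a few
minutes on one CPU.  All randomness flows from explicit seeds
(`numpy.random.default_rng` / `SeedSequence` children), so every table
is bit-reproducible.

## What the synthetic experiments show — and what they cannot

The generator reproduces the geometry- and resolution-driven behaviour
of the SV method: spill-out grows as spheres approach or exceed the rim
thickness, 2 mL spheres match 12–22 mm rims better than 4 mL spheres,
post-filtering moves the SV and WKP estimates relative to each other,
and NF correction removes the mean offset.  Passing tests demonstrate
internal consistency of the calibration-recovery-dose chain and the
statistics, not clinical accuracy.

Two deliberate simplifications change the *sign* and *ordering* of some
patient-data effects:

- **The emulator is linear.**  A Gaussian PSF can only redistribute
  counts, never overshoot, so on these phantoms the uncorrected SV
  method *under*-estimates the RC-corrected WKP dose (NF < 1 at every
  filter width).  In patients imaged with resolution-recovery OSEM at
  high update counts, edge overshoot and noise amplification push
  unfiltered SV readings *above* the reference (NF > 1, falling through
  unity at σ ≈ 5–6 mm).  The emulator deliberately omits those
  reconstruction nonlinearities, so the sign of the unfiltered bias is
  not transferable; the magnitude of the spread (accuracy) and its
  resolution dependence are the meaningful outputs.
- **Texture is voxel-wise.**  The lognormal uptake texture has no
  spatial correlation, so sphere means vary little within a kidney and
  the deterministic placement finds near-equivalent, well-matched
  locations.  With the best-scoring sphere used first, averaging in
  lower-ranked spheres cannot reduce — and for 4 mL spheres slightly
  increases — the across-kidney spread.  In patients, structured
  cortex/medulla heterogeneity and operator variability make individual
  spheres noisier and approximately exchangeable, which is why averaging
  several spheres helps there.  Conclusions about the *benefit of more
  spheres* therefore do not transfer from this generator.

Further limitations: no attenuation or scatter modelling, no
distance-dependent resolution, no respiratory motion, no tumours or
cysts, no spill-in from hot neighbouring organs (background is a flat
5%), no CT segmentation error, and no photon cross-dose.  These are all
candidates for extending the generator rather than properties of the
method under study.
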