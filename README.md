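# svdose — small-volume-of-interest kidney dosimetry for ¹⁷⁷Lu SPECT

Kidneys are the dose-limiting organ in ¹⁷⁷Lu-DOTATATE therapy of
neuroendocrine tumours, and per-cycle kidney dosimetry normally requires
manually segmenting the whole kidney parenchyma (WKP — cortex plus
medulla, excluding the renal pelvis) on every SPECT/CT time point.  The
*small-VOI* (SV) method replaces that segmentation with a few spheres
(4, 2 or 0.6 mL) dropped into representative regions of the parenchyma.
`svdose` is a desk-scale simulation laboratory for studying when, and
how well, that shortcut works: it generates digital kidney phantoms with
known activity and kinetics, emulates reconstructed SPECT images,
estimates absorbed doses with both methods, and quantifies their
agreement.

The package is aimed at medical-physics researchers evaluating
quantitative SPECT dosimetry protocols.

## The model

**Activity and dose.**  Each phantom kidney carries a uniform (optionally
textured) activity concentration with mono-exponential washout,
C(t) = C₀·exp(−λt).  VOI counts c(t) on an emulated image convert to a
concentration via the calibration chain

    C(t) = c(t) / (Q · RC(V) · V · ρ),        ρ = 1.05 g/mL,

where Q (cps/MBq) is the camera sensitivity measured on a uniform
cylinder phantom and RC is the recovery coefficient of the VOI — the
measured-to-true activity ratio that quantifies partial-volume
spill-out.  The SV variant uses RC = 1 and the sphere volume.  A
mono-exponential fit of the sampled C(t) is integrated from zero to
infinity (TIAC = C₀/λ) and converted to absorbed dose under the
local-energy-deposit assumption for the 147 keV mean electron energy per
¹⁷⁷Lu decay:

    D = TIAC × 0.08479 Gy per (MBq·h/g).

**Recovery.**  RC is simulated per kidney on noiseless emulation, and its
volume dependence is summarised by the two-parameter curve
RC(V) = 1/(1 + a/V)^b fitted by nonlinear least squares
(`RecoveryCurveModel`).  Two acquisition presets mirror clinical
reconstructions: `ASCC` (high resolution, calibrated so the mean RC over
a 36-kidney reference cohort is 0.85) and `AC` (the same response with
6 mm of extra Gaussian smoothing in quadrature, giving a mean RC of
about 0.66).

**Agreement.**  SV doses are normalised by the mean single-sphere dose
ratio NF = mean(D_SV/D_WKP) (an apparent recovery coefficient for the SV
method, estimated per sphere volume and filter width), and compared to
the WKP reference on the percentage-difference scale: the mean PD is the
*bias*, its SD the *accuracy*, with Bland-Altman limits of agreement at
bias ± 1.96 SD (`MethodComparison` → `AgreementResults`).

## Worked example

```python
import numpy as np
import svdose as sv
from svdose.phantoms import activity_at

model = sv.protocol_preset("ASCC").with_(postfilter_sigma_mm=4.0)
phantom = sv.make_kidney_phantom(
    volume_ml=120.0, thickness_mm=16.0, C0=0.6, lam=np.log(2) / 48.0,
    texture_cv=0.10, seed=7, kidney_id="demo",
)
rc = sv.simulate_rc(phantom.wkp_mask, model.with_(noise=False)).rc
print(f"recovery coefficient RC(V=120 mL) = {rc:.3f}")

images = {t: sv.acquire(activity_at(phantom, t), model.with_(noise=True, seed=int(t)))
          for t in (24.0, 48.0, 168.0)}
wkp = sv.estimate_dose(images, method="WKP", wkp=phantom.wkp_mask, rc=rc,
                       Q_cps_per_mbq=model.Q_cps_per_mbq, kidney_id="demo")
print(f"WKP dose = {wkp.dose_gy:.2f} Gy ({wkp.dose_rate_gy_per_gbq:.3f} Gy/GBq), "
      f"truth = {phantom.true_dose_gy():.2f} Gy")

svs = sv.place_svs(images[24.0], phantom.wkp_mask, sv_volume_ml=2.0, k=3)
est = sv.estimate_dose(images, method="SV", sv_set=svs, n_svs=3,
                       Q_cps_per_mbq=model.Q_cps_per_mbq, kidney_id="demo")
print(f"SV2 (3 spheres) dose = {est.dose_gy:.2f} Gy -> ratio to WKP = "
      f"{est.dose_gy/wkp.dose_gy:.3f}")
```

prints

```
recovery coefficient RC(V=120 mL) = 0.737
WKP dose = 3.51 Gy (0.475 Gy/GBq), truth = 3.52 Gy
SV2 (3 spheres) dose = 2.73 Gy -> ratio to WKP = 0.777
```

The RC-corrected WKP estimate recovers the ground-truth dose of this
120 mL kidney to better than 1%, while the uncorrected three-sphere SV
estimate reads 22% low on this 4-mm-filtered image — exactly the kind of
systematic offset the normalization factor absorbs.  At cohort level:

```python
cohort = sv.make_cohort(sv.CohortSpec(n_patients=6, seed=1))
doses, summary = sv.run_sweep(cohort, sv.protocol_preset("ASCC"),
                              sigmas_mm=(4.0,), sv_volumes_ml=(2.0,), seed=1)
```

and a `MethodComparison` of the three-sphere doses against the reference
prints

```
SV vs WKP method agreement
  kidneys          : 12
  evaluated dose   : normalized (D_SV / NF)
  NF (apparent RC) : 0.7850
  bias             : -0.00 %
  accuracy (SD PD) : 6.34 %
  Pearson r        : 0.984
  95% LoA          : [-12.43, +12.43] %
```

i.e. after NF correction the SV method is unbiased in-sample with a
per-kidney spread (accuracy) of about 6% on this synthetic cohort.

A command-line surface wraps the same pipeline:

```bash
svdose sweep --patients 18 --seed 7 --sigmas 0,4 --sv-volumes 4,2,0.6 --out runs/demo
svdose report --sweep runs/demo/sweep.csv --sigma 4
```

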