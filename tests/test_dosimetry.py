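"""Calibration factor, concentration, kinetics and absorbed dose."""

import math

import numpy as np
import pytest

import svdose as sv
from svdose.dosimetry import (
    DOSE_PER_TIAC_GY,
    DoseEstimate,
    MonoExpModel,
    tiac_by_quadrature,
)
from svdose.grids import MaskVOI, VoxelImage
from svdose.phantoms import activity_at


@pytest.fixture(scope="module")
def calibration():
    truth, voi = sv.make_calibration_phantom(100.0, 6000.0, voi_margin_mm=25.0)
    conc = truth.values.max()  # uniform interior concentration (MBq/mL)
    return truth, voi, conc * voi.volume_ml


def test_calibrated_q_is_exact_without_blur(calibration):
    truth, voi, true_in_voi = calibration
    img = sv.acquire(truth, sv.AcquisitionModel(system_sigma_mm=0.0, Q_cps_per_mbq=10.0))
    assert sv.calibrate_Q(img, voi, true_in_voi) == pytest.approx(10.0, rel=1e-12)


def test_calibrated_q_survives_blur(calibration):
    """Interior VOI: spill-in balances spill-out, Q error < 0.5%."""
    truth, voi, true_in_voi = calibration
    img = sv.acquire(truth, sv.AcquisitionModel(system_sigma_mm=4.0, Q_cps_per_mbq=10.0))
    assert sv.calibrate_Q(img, voi, true_in_voi) == pytest.approx(10.0, rel=0.005)


def test_calibrated_q_unbiased_under_noise(calibration):
    truth, voi, true_in_voi = calibration
    base = sv.AcquisitionModel(system_sigma_mm=4.0, Q_cps_per_mbq=10.0, acq_time_s=600.0)
    qs = [
        sv.calibrate_Q(sv.acquire(truth, base.with_(noise=True, seed=s)), voi, true_in_voi)
        for s in range(30)
    ]
    se = np.std(qs, ddof=1) / math.sqrt(len(qs))
    assert abs(np.mean(qs) - 10.0) <= 3 * se


def test_calibrate_q_rejects_zero_activity(calibration):
    truth, voi, _ = calibration
    img = sv.acquire(truth, sv.AcquisitionModel(system_sigma_mm=0.0))
    with pytest.raises(ValueError):
        sv.calibrate_Q(img, voi, 0.0)


def test_concentration_hand_value():
    # 1000 / (10 * 0.85 * 100 * 1.05) = 1.1204 MBq/g
    assert sv.concentration(1000.0, 10.0, 0.85, 100.0, 1.05) == pytest.approx(
        1.1204, abs=2e-4
    )
    assert sv.concentration(7.3, 1.0, 1.0, 1.0, 1.0) == 7.3  # identity case
    assert sv.concentration(100.0, 10.0, 0.4, 50.0) == pytest.approx(
        2.0 * sv.concentration(100.0, 10.0, 0.8, 50.0)
    )


def test_concentration_names_offending_argument():
    with pytest.raises(ValueError, match="rc"):
        sv.concentration(100.0, 10.0, 0.0, 50.0)
    with pytest.raises(ValueError, match="volume"):
        sv.concentration(100.0, 10.0, 0.9, -5.0)
    with pytest.raises(ValueError, match="<= 1.05"):
        sv.concentration(100.0, 10.0, 1.2, 50.0)


def test_sv_concentration_is_rc_free_eq2():
    assert sv.sv_concentration(55.0, 10.0, 4.0) == sv.concentration(
        55.0, 10.0, 1.0, 4.0
    )


def test_sv_concentration_exact_in_uniform_medium():
    """Blur of a constant is the constant: a sphere deep inside a uniform
    region reads the true concentration regardless of resolution."""
    conc_true = 0.8  # MBq/mL
    img = VoxelImage(np.full((30, 30, 30), conc_true), 4.42)
    model = sv.AcquisitionModel(system_sigma_mm=5.0, Q_cps_per_mbq=10.0)
    counts = sv.acquire(img, model)
    voi = sv.sphere_voi(tuple(np.array(img.origin) + 4.42 * 14.5), 4.0, img)
    c = sv.sv_concentration(sv.voi_counts(counts, voi), 10.0, voi.volume_ml, 1.0)
    assert c == pytest.approx(conc_true, rel=2e-3)


def test_sv4_underreads_thin_rim(ascc):
    """A 4-mL sphere straddling a thin parenchyma rim dilutes the signal:
    measured SV concentration falls below the true rim concentration."""
    ph = sv.make_kidney_phantom(100.0, 12.0, kidney_id="thin")
    img = sv.acquire(activity_at(ph, 0.0), ascc)
    placed = sv.place_svs(img, ph.wkp_mask, 4.0, k=1)
    c = sv.sv_concentration(
        sv.voi_counts(img, placed.masks[0]), ascc.Q_cps_per_mbq, 4.0
    )
    assert c < ph.C0


def test_monoexp_exact_recovery_both_methods():
    t = np.array([24.0, 48.0, 168.0])
    c0, lam = 1.0, math.log(2) / 48.0
    c = c0 * np.exp(-lam * t)
    for method in ("nls", "loglinear"):
        fit = MonoExpModel(t, c).fit(method=method)
        assert fit.C0 == pytest.approx(c0, rel=1e-10)
        assert fit.lam == pytest.approx(lam, rel=1e-10)
    assert "TIAC" in fit.summary()


def test_monoexp_degenerate_inputs():
    with pytest.raises(ValueError, match="decay"):
        MonoExpModel([24.0, 48.0, 168.0], [1.0, 1.0, 1.0]).fit()
    with pytest.raises(ValueError, match="distinct"):
        MonoExpModel([24.0, 24.0], [1.0, 0.5]).fit()
    with pytest.raises(ValueError, match="positive"):
        MonoExpModel([24.0, 48.0], [1.0, 0.0]).fit()
    with pytest.raises(ValueError, match="method"):
        MonoExpModel([24.0, 48.0], [1.0, 0.5]).fit(method="spline")


def test_monoexp_noisy_rate_recovery():
    """5% multiplicative noise, 3 points: median rate error < 10%."""
    t = np.array([24.0, 48.0, 168.0])
    lam = math.log(2) / 48.0
    clean = 0.6 * np.exp(-lam * t)
    errs = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        fit = MonoExpModel(t, clean * (1 + rng.normal(0, 0.05, 3))).fit()
        errs.append(abs(fit.lam / lam - 1))
    assert np.median(errs) < 0.10


def test_tiac_closed_form_and_quadrature():
    fit = MonoExpModel([24.0, 48.0], [1.0 * math.exp(-math.log(2) / 48 * t) for t in (24.0, 48.0)]).fit()
    assert sv.tiac(fit) == pytest.approx(48.0 / math.log(2), rel=1e-9)
    assert sv.tiac(fit) == pytest.approx(69.25, abs=0.01)
    assert tiac_by_quadrature(fit) == pytest.approx(sv.tiac(fit), rel=1e-3)
    assert sv.tiac(fit) * DOSE_PER_TIAC_GY == sv.dose(sv.tiac(fit))


def test_dose_constant_from_first_principles():
    # 3.6e9 decays/(MBq h) * 147 keV * 1.602177e-16 J/keV * 1000 g/kg
    k = 3.6e9 * 147.0 * 1.602177e-16 * 1000.0
    assert DOSE_PER_TIAC_GY == pytest.approx(k, rel=1e-12)
    assert DOSE_PER_TIAC_GY == pytest.approx(0.08479, abs=5e-6)
    assert sv.dose(0.0) == 0.0
    assert sv.dose(2.0) == 2.0 * sv.dose(1.0)
    with pytest.raises(ValueError):
        sv.dose(-1.0)


def test_dose_estimate_requires_consistent_dose():
    with pytest.raises(ValueError, match="TIAC"):
        DoseEstimate("k", "WKP", 0, 10.0, 1.0, 0.1)


def test_wkp_dose_recovers_truth_with_simulated_rc(ascc, kidney_100):
    rc = sv.simulate_rc(kidney_100.wkp_mask, ascc).rc
    imgs = {t: sv.acquire(activity_at(kidney_100, t), ascc) for t in (24.0, 48.0, 168.0)}
    est = sv.estimate_dose(
        imgs, method="WKP", wkp=kidney_100.wkp_mask, rc=rc,
        Q_cps_per_mbq=ascc.Q_cps_per_mbq, kidney_id=kidney_100.kidney_id,
    )
    assert est.dose_gy == pytest.approx(kidney_100.true_dose_gy(), rel=1e-6)
    assert est.dose_rate_gy_per_gbq == pytest.approx(est.dose_gy / 7.4)


def test_wkp_and_sv_agree_in_uniform_infinite_medium():
    """No spatial structure, no partial volume: both methods read the
    same concentration, independent of the PSF width."""
    conc = 0.5
    img = VoxelImage(np.full((26, 26, 26), conc), 4.42)
    lam = math.log(2) / 50.0
    model = sv.AcquisitionModel(system_sigma_mm=6.0, Q_cps_per_mbq=10.0)
    images = {
        t: sv.acquire(img.with_values(img.values * math.exp(-lam * t)), model)
        for t in (24.0, 72.0)
    }
    center = tuple(np.array(img.origin) + 4.42 * 12.5)
    box = np.zeros(img.shape)
    box[9:17, 9:17, 9:17] = 1.0
    wkp = MaskVOI(box, img.spacing, origin=img.origin)
    sphere = sv.sphere_voi(center, 4.0, img)
    sv_set = sv.SVSet(centers_mm=[center], sv_volume_ml=4.0, masks=[sphere])
    common = dict(Q_cps_per_mbq=10.0, rho_g_per_ml=1.0)
    wkp_est = sv.estimate_dose(images, method="WKP", wkp=wkp, rc=1.0, **common)
    sv_est = sv.estimate_dose(images, method="SV", sv_set=sv_set, **common)
    assert sv_est.dose_gy == pytest.approx(wkp_est.dose_gy, rel=1e-9)


def test_dose_chain_is_scale_equivariant(ascc, kidney_100):
    rc = sv.simulate_rc(kidney_100.wkp_mask, ascc).rc
    imgs = {t: sv.acquire(activity_at(kidney_100, t), ascc) for t in (24.0, 48.0)}
    alpha = 3.7
    scaled = {t: im.with_values(alpha * im.values) for t, im in imgs.items()}
    kwargs = dict(method="WKP", wkp=kidney_100.wkp_mask, rc=rc, Q_cps_per_mbq=10.0)
    base = sv.estimate_dose(imgs, **kwargs)
    big = sv.estimate_dose(scaled, **kwargs)
    assert big.dose_gy == pytest.approx(alpha * base.dose_gy, rel=1e-9)


def test_estimate_dose_argument_validation(ascc, kidney_100):
    imgs = {24.0: sv.acquire(activity_at(kidney_100, 24.0), ascc)}
    with pytest.raises(ValueError, match="2 time points"):
        sv.estimate_dose(imgs, method="WKP", wkp=kidney_100.wkp_mask, rc=0.9,
                         Q_cps_per_mbq=10.0)
    imgs[48.0] = sv.acquire(activity_at(kidney_100, 48.0), ascc)
    with pytest.raises(ValueError, match="rc"):
        sv.estimate_dose(imgs, method="WKP", wkp=kidney_100.wkp_mask,
                         Q_cps_per_mbq=10.0)
    with pytest.raises(ValueError, match="SVSet"):
        sv.estimate_dose(imgs, method="SV", Q_cps_per_mbq=10.0)
    with pytest.raises(ValueError, match="unknown method"):
        sv.estimate_dose(imgs, method="planar", Q_cps_per_mbq=10.0)
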