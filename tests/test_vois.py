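"""Sphere VOIs, count summation and representative placement."""

import numpy as np
import pytest

import svdose as sv
from svdose.grids import GridAlignmentError, MaskVOI, VoxelImage
from svdose.phantoms import activity_at


@pytest.fixture(scope="module")
def grid():
    return VoxelImage(np.zeros((24, 24, 24)), 4.42, origin=(-50.0, -50.0, -50.0))


@pytest.mark.parametrize("volume", [4.0, 2.0, 0.6])
def test_sphere_voi_volume_accuracy(volume, grid):
    voi = sv.sphere_voi((0.0, 0.0, 0.0), volume, grid)
    assert voi.volume_ml == pytest.approx(volume, rel=0.005)
    assert voi.volume_ml == pytest.approx(volume, abs=0.02)


def test_sphere_weights_saturate_for_huge_sphere(grid):
    voi = sv.sphere_voi((0.0, 0.0, 0.0), 5000.0, grid)
    assert np.all(voi.weights == 1.0)  # grid entirely inside the sphere


def test_sphere_center_outside_grid_rejected(grid):
    with pytest.raises(ValueError, match="outside"):
        sv.sphere_voi((500.0, 0.0, 0.0), 4.0, grid)


def test_voi_counts_matches_bruteforce_loop(grid):
    rng = np.random.default_rng(5)
    img = grid.with_values(rng.random(grid.shape))
    voi = sv.sphere_voi((4.0, -6.0, 2.0), 4.0, img)
    brute = 0.0
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            for k in range(img.shape[2]):
                brute += img.values[i, j, k] * voi.weights[i, j, k]
    assert sv.voi_counts(img, voi) == pytest.approx(brute, rel=1e-12)
    assert sv.voi_counts(img.with_values(np.zeros(img.shape)), voi) == 0.0


def test_voi_counts_uniform_image(grid):
    img = grid.with_values(np.full(grid.shape, 2.5))
    voi = sv.sphere_voi((0.0, 0.0, 0.0), 2.0, img)
    assert sv.voi_counts(img, voi) == pytest.approx(2.5 * voi.weights.sum())


def test_voi_counts_rejects_mismatched_grids(grid):
    other = VoxelImage(np.zeros((24, 24, 24)), 4.0, origin=(-50.0, -50.0, -50.0))
    voi = sv.sphere_voi((0.0, 0.0, 0.0), 2.0, grid)
    with pytest.raises(GridAlignmentError):
        sv.voi_counts(other, voi)


@pytest.fixture(scope="module")
def kidney_image(ascc, kidney_100):
    return sv.acquire(activity_at(kidney_100, 0.0), ascc)


def test_placement_is_deterministic(kidney_image, kidney_100):
    a = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=4)
    b = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=4)
    assert a.centers_mm == b.centers_mm
    assert a.scores == b.scores


def test_placement_greedy_prefix_is_nested(kidney_image, kidney_100):
    k3 = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=3)
    k5 = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=5)
    assert k5.centers_mm[:3] == k3.centers_mm


def test_placement_on_constant_image_follows_tie_break(kidney_100):
    """All candidates score zero on a constant image, so the first pick
    is the lowest linear voxel index among inner-half candidates."""
    from scipy import ndimage

    mask = kidney_100.wkp_mask
    img = kidney_100.truth_image.with_values(np.ones(mask.shape))
    placed = sv.place_svs(img, mask, 0.6, k=1)
    binary = mask.weights >= 0.5
    dist = ndimage.distance_transform_edt(binary, sampling=mask.spacing)
    inner = binary & (dist >= 0.5 * dist.max())
    first_flat = int(np.flatnonzero(inner.ravel())[0])
    expected = tuple(
        o + s * i
        for o, s, i in zip(
            img.origin, img.spacing, np.unravel_index(first_flat, img.shape)
        )
    )
    assert placed.centers_mm[0] == pytest.approx(expected)
    assert placed.scores[0] <= 1e-12


def test_placement_avoids_artificial_hotspot(kidney_image, kidney_100):
    base = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=3)
    hot = kidney_image.values.copy()
    ci = tuple(
        int(round((c - o) / s))
        for c, o, s in zip(base.centers_mm[0], kidney_image.origin, kidney_image.spacing)
    )
    hot[ci] *= 5.0
    shifted = sv.place_svs(
        kidney_image.with_values(hot), kidney_100.wkp_mask, 2.0, k=3
    )
    assert base.centers_mm[0] not in shifted.centers_mm


def test_placement_reports_incomplete_sets(kidney_image, kidney_100):
    placed = sv.place_svs(
        kidney_image, kidney_100.wkp_mask, 4.0, k=5, min_sep_mm=500.0
    )
    assert len(placed) == 1
    assert placed.incomplete


def test_selected_sphere_means_track_wkp_median(kidney_image, kidney_100):
    """On a uniform-uptake kidney the chosen spheres' mean count rates sit
    close to the parenchyma median (the representativeness target)."""
    placed = sv.place_svs(kidney_image, kidney_100.wkp_mask, 2.0, k=3)
    binary = kidney_100.wkp_mask.weights >= 0.5
    median = np.median(kidney_image.values[binary])
    for mask in placed.masks:
        mean = sv.voi_counts(kidney_image, mask) / mask.weights.sum()
        assert abs(mean - median) <= 0.15 * median


def test_wkp_from_mask_volume_and_additivity(kidney_100):
    volume, mask = sv.wkp_from_mask(kidney_100.wkp_mask)
    assert volume == pytest.approx(100.0, rel=0.02)
    assert mask is kidney_100.wkp_mask

    half_a = MaskVOI(
        np.where(np.arange(mask.shape[0])[:, None, None] < mask.shape[0] // 2,
                 mask.weights, 0.0),
        mask.spacing, origin=mask.origin,
    )
    half_b = MaskVOI(
        np.where(np.arange(mask.shape[0])[:, None, None] >= mask.shape[0] // 2,
                 mask.weights, 0.0),
        mask.spacing, origin=mask.origin,
    )
    assert half_a.volume_ml + half_b.volume_ml == pytest.approx(volume, rel=1e-12)

    with pytest.raises(ValueError, match="empty"):
        sv.wkp_from_mask(MaskVOI(np.zeros(mask.shape), mask.spacing))


def test_volume_invariant_under_grid_translation(kidney_100):
    mask = kidney_100.wkp_mask
    rolled = MaskVOI(np.roll(mask.weights, 1, axis=0), mask.spacing,
                     origin=mask.origin)
    assert rolled.volume_ml == pytest.approx(mask.volume_ml, rel=1e-12)
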