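"""Median aortic HU, thoracic bounds, and edge-touch detection."""

import numpy as np
import pytest

from aortaselect.geometry import ImageVolume, VolumeGeometry
from aortaselect.metrics import (
    MetricUndefined,
    aorta_complete,
    edge_touch_flags,
    median_hu,
    thoracic_bounds,
)
from aortaselect.segmentation import LabelMask

from conftest import random_mask_and_volume


def _geom(size):
    return VolumeGeometry((0, 0, 0), (1, 1, 1), np.eye(3), size)


def _mask(size, where):
    vox = np.zeros(size, bool)
    vox[where] = True
    return LabelMask("aorta", _geom(size), vox)


def brute_force_median(volume, mask, bounds):
    lo, hi = bounds
    vals = []
    nx, ny, nz = mask.geometry.size
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask.voxels[i, j, k] and lo <= k <= hi:
                    vals.append(volume.voxels[i, j, k])
    vals.sort()
    n = len(vals)
    if n == 0:
        return None
    if n % 2:
        return vals[n // 2]
    return 0.5 * (vals[n // 2 - 1] + vals[n // 2])


def brute_force_edges(mask):
    """Scan all six boundary planes; report only cranial and +/-x faces."""
    m = mask.voxels
    cranial = any(
        m[i, j, m.shape[2] - 1] for i in range(m.shape[0]) for j in range(m.shape[1])
    )
    lateral = any(
        m[0, j, k] or m[m.shape[0] - 1, j, k]
        for j in range(m.shape[1])
        for k in range(m.shape[2])
    )
    return cranial, lateral


# -- thoracic bounds --------------------------------------------------------


def test_thoracic_bounds_min_max_of_occupied_slices():
    lungs = LabelMask("lungs_composite", _geom((4, 4, 120)),
                      np.zeros((4, 4, 120), bool))
    lungs.voxels[1, 1, 10:81] = True
    assert thoracic_bounds(lungs) == (10, 80)
    assert thoracic_bounds(lungs, margin_slices=2) == (8, 82)


def test_thoracic_bounds_clipped_at_volume_edge():
    lungs = _mask((4, 4, 10), (1, 1, 0))
    assert thoracic_bounds(lungs, margin_slices=2) == (0, 2)


def test_thoracic_bounds_empty_mask_is_undefined():
    lungs = LabelMask("lungs_composite", _geom((4, 4, 4)), np.zeros((4, 4, 4), bool))
    with pytest.raises(MetricUndefined):
        thoracic_bounds(lungs)


# -- median HU --------------------------------------------------------------


def test_median_constant_field():
    size = (6, 6, 6)
    vol = ImageVolume(_geom(size), np.full(size, 320.0))
    mask = _mask(size, (slice(1, 4), slice(1, 4), slice(1, 4)))
    assert median_hu(vol, mask, (0, 5)) == 320.0


def test_median_even_count_mid_pair_mean():
    """Ten voxels, five at 400 and five at 60: mid-pair mean is 230."""
    size = (10, 1, 1)
    vox = np.array([400.0] * 5 + [60.0] * 5).reshape(size)
    vol = ImageVolume(_geom(size), vox)
    mask = LabelMask("aorta", _geom(size), np.ones(size, bool))
    assert median_hu(vol, mask, (0, 0)) == 230.0


def test_median_respects_slice_bounds():
    size = (2, 2, 10)
    vox = np.zeros(size)
    vox[..., :5] = 100.0
    vox[..., 5:] = 500.0
    vol = ImageVolume(_geom(size), vox)
    mask = LabelMask("aorta", _geom(size), np.ones(size, bool))
    assert median_hu(vol, mask, (0, 4)) == 100.0
    assert median_hu(vol, mask, (5, 9)) == 500.0


def test_median_empty_in_bounds_mask_is_undefined():
    size = (4, 4, 8)
    vol = ImageVolume(_geom(size), np.zeros(size))
    mask = _mask(size, (1, 1, 7))
    with pytest.raises(MetricUndefined):
        median_hu(vol, mask, (0, 3))


def test_median_matches_brute_force_on_random_inputs():
    rng = np.random.default_rng(123)
    checked = 0
    for _ in range(200):
        vol, mask = random_mask_and_volume(rng, max_side=8)
        nz = mask.geometry.size[2]
        lo = int(rng.integers(0, nz))
        hi = int(rng.integers(lo, nz))
        expected = brute_force_median(vol, mask, (lo, hi))
        if expected is None:
            with pytest.raises(MetricUndefined):
                median_hu(vol, mask, (lo, hi))
        else:
            assert median_hu(vol, mask, (lo, hi)) == expected
            checked += 1
    assert checked > 100


def test_median_shift_equivariance():
    """Adding a constant c to every in-mask voxel shifts the median by c."""
    rng = np.random.default_rng(9)
    vol, mask = random_mask_and_volume(rng, max_side=8)
    if not mask.voxels.any():
        mask.voxels[0, 0, 0] = True
    bounds = (0, mask.geometry.size[2] - 1)
    base = median_hu(vol, mask, bounds)
    shifted = ImageVolume(vol.geometry, vol.voxels + 250.0)
    assert median_hu(shifted, mask, bounds) == pytest.approx(base + 250.0)


def test_two_population_median_crosses_threshold_at_half():
    """Mixing thrombus-valued voxels past 50% flips the median across 150."""
    size = (100, 1, 1)
    geom = _geom(size)
    for frac, expect_above in [(0.25, True), (0.49, True), (0.51, False), (0.75, False)]:
        n_th = int(round(100 * frac))
        vox = np.array([60.0] * n_th + [320.0] * (100 - n_th)).reshape(size)
        vol = ImageVolume(geom, vox)
        mask = LabelMask("aorta", geom, np.ones(size, bool))
        assert (median_hu(vol, mask, (0, 0)) > 150.0) is expect_above


# -- edge touch -------------------------------------------------------------


def test_edge_cranial_touch():
    mask = _mask((6, 6, 6), (3, 3, 5))
    assert edge_touch_flags(mask, mask.geometry) == (True, False)


def test_edge_lateral_touch():
    mask = _mask((6, 6, 6), (0, 3, 3))
    assert edge_touch_flags(mask, mask.geometry) == (False, True)


def test_interior_mask_touches_nothing():
    mask = _mask((6, 6, 6), (slice(2, 4), slice(2, 4), slice(2, 4)))
    assert edge_touch_flags(mask, mask.geometry) == (False, False)


def test_caudal_and_ap_touches_are_ignored():
    """The descending aorta exits the chest caudally; that must not exclude."""
    caudal = _mask((6, 6, 6), (3, 3, 0))
    assert edge_touch_flags(caudal, caudal.geometry) == (False, False)
    posterior = _mask((6, 6, 6), (3, 5, 3))
    assert edge_touch_flags(posterior, posterior.geometry) == (False, False)


def test_edge_buffer_widens_detection():
    one_in = _mask((8, 8, 8), (1, 4, 4))
    assert edge_touch_flags(one_in, one_in.geometry) == (False, False)
    assert edge_touch_flags(one_in, one_in.geometry, buffer_voxels=1) == (False, True)


def test_edge_flags_match_brute_force_on_random_masks():
    rng = np.random.default_rng(321)
    for _ in range(300):
        _, mask = random_mask_and_volume(rng, max_side=7)
        if not mask.voxels.any():
            continue
        assert edge_touch_flags(mask, mask.geometry) == brute_force_edges(mask)


def test_edge_flags_flipped_z_axis():
    """With the slice axis pointing caudally, slice 0 is the cranial one."""
    size = (6, 6, 6)
    geom = VolumeGeometry((0, 0, 0), (1, 1, 1),
                          np.diag([1.0, -1.0, -1.0]), size)
    vox = np.zeros(size, bool)
    vox[3, 3, 0] = True  # slice 0 now has the maximal patient z
    assert edge_touch_flags(LabelMask("aorta", geom, vox), geom) == (True, False)


def test_aorta_complete_truth_table():
    assert aorta_complete((False, False))
    assert not aorta_complete((True, False))
    assert not aorta_complete((False, True))
    assert not aorta_complete((True, True))
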