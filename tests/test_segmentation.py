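"""Backend contract, mask resampling, and label presence."""

import warnings

import numpy as np
import pytest

from aortaselect.geometry import VolumeGeometry
from aortaselect.phantom import PhantomSpec, generate_phantom
from aortaselect.segmentation import (
    LABELS,
    BackendConfig,
    ExternalAdapter,
    LabelMask,
    OracleBackend,
    SegmentationFailure,
    label_present,
    resample_mask_to_grid,
    segment,
)

from conftest import random_mask_and_volume


def test_oracle_identity_at_native_spacing(good_phantom):
    """At the native grid spacing the oracle returns the stored masks exactly."""
    volume, truth = good_phantom
    config = BackendConfig(
        backend_id="oracle",
        working_spacing=1.5,
        oracle_masks={volume.provenance: truth.masks},
    )
    result = segment(volume, config)
    for label in LABELS:
        assert np.array_equal(result.masks[label].voxels, truth.masks[label].voxels)


def test_oracle_missing_anatomy_yields_empty_mask():
    volume, truth = generate_phantom(
        PhantomSpec(include_brachiocephalic=False, seed=3)
    )
    config = BackendConfig(
        backend_id="oracle", oracle_masks={volume.provenance: truth.masks}
    )
    result = segment(volume, config)
    assert result.masks["brachiocephalic_trunk"].count == 0
    assert result.masks["aorta"].count > 0


def test_oracle_unknown_series_fails(good_phantom):
    volume, _ = good_phantom
    config = BackendConfig(backend_id="oracle", oracle_masks={})
    with pytest.raises(SegmentationFailure):
        segment(volume, config)


def test_external_adapter_unavailable_raises(good_phantom):
    volume, _ = good_phantom
    config = BackendConfig(
        backend_id="external_adapter", executable="no-such-segmenter-exe"
    )
    with pytest.raises(SegmentationFailure):
        ExternalAdapter(config).segment(volume)


def _iso_geom(size, spacing, origin=(0.0, 0.0, 0.0)):
    return VolumeGeometry(origin=origin, spacing=(spacing,) * 3,
                          direction=np.eye(3), size=size)


def test_resample_identity_target():
    rng = np.random.default_rng(0)
    _, mask = random_mask_and_volume(rng)
    out = resample_mask_to_grid(mask, mask.geometry)
    assert np.array_equal(out.voxels, mask.voxels)


def test_resample_cylinder_voxel_count_scales_with_grid():
    """A 30 mm cylinder on a 3 mm grid gains ~8x voxels on a 1.5 mm grid."""
    coarse = _iso_geom((20, 20, 20), 3.0)
    centers = coarse.voxel_centers()
    x, y = centers[..., 0] - 30.0, centers[..., 1] - 30.0
    cyl = (x * x + y * y) <= 15.0**2
    mask = LabelMask("aorta", coarse, cyl)
    fine = _iso_geom((40, 40, 40), 1.5)
    out = resample_mask_to_grid(mask, fine)
    ratio = out.count / mask.count
    assert 8.0 * 0.7 <= ratio <= 8.0 * 1.3


def test_resample_preserves_emptiness():
    geom = _iso_geom((5, 5, 5), 2.0)
    empty = LabelMask("aorta", geom, np.zeros((5, 5, 5), bool))
    assert resample_mask_to_grid(empty, _iso_geom((10, 10, 10), 1.0)).count == 0


def test_resample_disjoint_extents_warns():
    geom = _iso_geom((4, 4, 4), 1.0)
    mask = LabelMask("aorta", geom, np.ones((4, 4, 4), bool))
    far = _iso_geom((4, 4, 4), 1.0, origin=(100.0, 100.0, 100.0))
    with pytest.warns(UserWarning):
        out = resample_mask_to_grid(mask, far)
    assert out.count == 0


def test_resample_never_creates_voxels_outside_dilated_bbox():
    """Output stays inside the source patient bbox dilated by one target voxel."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        _, mask = random_mask_and_volume(rng)
        if not mask.voxels.any():
            continue
        target = _iso_geom(
            tuple(int(rng.integers(4, 16)) for _ in range(3)),
            float(rng.uniform(0.5, 3.0)),
            origin=tuple(rng.uniform(-3, 3, 3)),
        )
        with warnings.catch_warnings():
            # a random target may legitimately be disjoint from the source
            warnings.simplefilter("ignore", UserWarning)
            out = resample_mask_to_grid(mask, target)
        if not out.voxels.any():
            continue
        src_pts = mask.geometry.voxel_centers()[mask.voxels]
        lo = src_pts.min(axis=0) - np.max(mask.geometry.spacing) / 2
        hi = src_pts.max(axis=0) + np.max(mask.geometry.spacing) / 2
        pad = np.max(target.spacing)
        out_pts = target.voxel_centers()[out.voxels]
        assert np.all(out_pts >= lo - pad) and np.all(out_pts <= hi + pad)


def test_resample_agrees_with_sitk_nearest_neighbor():
    """Independent cross-check of the NN resampler against SimpleITK."""
    sitk = pytest.importorskip("SimpleITK")
    rng = np.random.default_rng(7)
    src = _iso_geom((12, 10, 8), 2.0, origin=(1.0, -2.0, 0.5))
    vox = rng.random(src.size) < 0.4
    mask = LabelMask("aorta", src, vox)
    target = _iso_geom((20, 16, 14), 1.37, origin=(0.21, -1.13, 0.43))

    ours = resample_mask_to_grid(mask, target)

    img = sitk.GetImageFromArray(np.transpose(vox.astype(np.uint8), (2, 1, 0)))
    img.SetSpacing(src.spacing)
    img.SetOrigin(src.origin)
    ref = sitk.Image(list(target.size), sitk.sitkUInt8)
    ref.SetSpacing(target.spacing)
    ref.SetOrigin(target.origin)
    res = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0)
    theirs = np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0)).astype(bool)

    # compare only where the conventions provably agree: strictly interior
    # points (we deliberately keep the half-voxel boundary shell that ITK
    # drops) that are not exact rounding ties (numpy rounds half to even,
    # ITK half up)
    cont = src.patient_to_voxel(target.voxel_centers().reshape(-1, 3))
    interior = np.all((cont >= 0.0) & (cont <= np.asarray(src.size) - 1.0), axis=1)
    no_tie = np.all(np.abs(cont - np.floor(cont) - 0.5) > 1e-9, axis=1)
    strict = (interior & no_tie).reshape(target.size)
    assert strict.sum() > 1000  # the comparison is not vacuous
    assert np.array_equal(ours.voxels[strict], theirs[strict])


def test_label_present_thresholds():
    geom = _iso_geom((10, 10, 10), 1.0)
    vox = np.zeros((10, 10, 10), bool)
    vox.flat[:5] = True
    speckle = LabelMask("aorta", geom, vox)
    assert not label_present(speckle)  # below the 10-voxel floor
    assert label_present(speckle, min_voxels=5)
    vox.flat[:500] = True
    assert label_present(LabelMask("aorta", geom, vox))
    assert not label_present(LabelMask("aorta", geom, np.zeros((10, 10, 10), bool)))
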