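"""Series discovery, orientation classification, spacing, and volume loading."""

import json

import numpy as np
import pydicom
import pytest
from hypothesis import given, strategies as st

from aortaselect.imaging import (
    CorruptSeriesError,
    classify_orientation,
    compute_slice_spacing,
    is_volumetric,
    load_volume,
    scan_directory,
)
from aortaselect.phantom import PhantomSpec, StudySpec, CohortSpec, generate_cohort


@pytest.mark.parametrize(
    "row, col, expected",
    [
        ((1, 0, 0), (0, 1, 0), "axial"),
        ((1, 0, 0), (0, 0, -1), "coronal"),
        ((0, 1, 0), (0, 0, -1), "sagittal"),
        # in-plane rotation by ~5.7 deg leaves the normal on +z
        ((0.995, 0.0998, 0), (-0.0998, 0.995, 0), "axial"),
        # 45 deg tilt about x: between axial and coronal
        ((1, 0, 0), (0, 0.7071, -0.7071), "oblique"),
        ((2, 0, 0), (0, 1, 0), "unknown"),  # non-unit row cosine
        ((float("nan"), 0, 0), (0, 1, 0), "unknown"),
    ],
)
def test_orientation_classes(row, col, expected):
    assert classify_orientation(row, col) == expected


@given(angle=st.floats(0, 2 * np.pi, allow_nan=False))
def test_orientation_invariant_under_inplane_rotation(angle):
    """Rotating row/col cosines within the slice plane keeps the normal fixed."""
    c, s = np.cos(angle), np.sin(angle)
    row = (c, s, 0.0)
    col = (-s, c, 0.0)
    assert classify_orientation(row, col) == "axial"


@pytest.mark.parametrize(
    "positions, expected",
    [
        ([0, 2, 4, 6], (2.0, True)),
        ([0, 2, 5], (2.5, False)),  # gaps {2,3}: median 2.5, deviation >10%
        ([6, 0, 2, 4], (2.0, True)),  # order-insensitive
    ],
)
def test_slice_spacing(positions, expected):
    assert compute_slice_spacing(positions) == expected


def test_slice_spacing_degenerate():
    assert compute_slice_spacing([3.0]) is None


def test_volumetric_thresholds():
    from aortaselect.imaging import SeriesRecord

    def rec(n, modality="CT"):
        return SeriesRecord("s", "st", "p", modality, [], n)

    assert is_volumetric(rec(300))
    assert not is_volumetric(rec(1))       # scout/localizer
    assert not is_volumetric(rec(19))      # below the configurable minimum
    assert is_volumetric(rec(19), min_slices=10)
    assert not is_volumetric(rec(300, modality="MR"))


def test_scan_round_trip_nifti(small_cohort):
    out, bundle = small_cohort
    scan = scan_directory(out, dialect="nifti_sidecar")
    assert len(scan.studies) == 13
    assert scan.n_series == len(bundle) == 14
    assert not scan.skipped
    # grouping: paired study has two series under one study record
    by_n = sorted(len(s.series) for s in scan.studies)
    assert by_n == [1] * 12 + [2]


def test_scan_skips_garbage_file(tmp_path):
    """A corrupted file is logged and does not change the cohort."""
    spec = CohortSpec(
        [StudySpec("stA", "p", [PhantomSpec(series_uid="stA-s0", study_uid="stA")])]
    )
    generate_cohort(spec, tmp_path, dialect="dicom")
    clean = scan_directory(tmp_path, dialect="dicom")
    (tmp_path / "stA" / "garbage.dcm").write_bytes(b"not a dicom file")
    scan = scan_directory(tmp_path, dialect="dicom")
    assert len(scan.studies) == len(clean.studies) == 1
    assert scan.n_series == clean.n_series == 1
    assert [s.reason for s in scan.skipped] == ["unreadable_dicom"]
    # conservation: series found + skips == candidate files grouped per series
    n_candidates_series = 1 + 1  # one readable series + one junk "series" file
    assert scan.n_series + len(scan.skipped) == n_candidates_series


def test_scan_empty_directory_warns(tmp_path):
    with pytest.warns(UserWarning):
        scan = scan_directory(tmp_path, dialect="dicom")
    assert scan.studies == []


def test_nifti_without_sidecar_is_skipped(tmp_path):
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.zeros((4, 4, 4), np.float32), np.eye(4)),
             tmp_path / "orphan.nii")
    with pytest.warns(UserWarning):
        scan = scan_directory(tmp_path, dialect="nifti_sidecar")
    assert [s.reason for s in scan.skipped] == ["missing_sidecar"]


def _tiny_dicom_cohort(tmp_path, n_slices=3):
    spec = CohortSpec([
        StudySpec("stB", "p", [
            # a 3-slice stack cannot show the whole aorta: flag it truncated
            PhantomSpec(series_uid="stB-s0", study_uid="stB",
                        n_slices=n_slices, noise_sd=0.0,
                        truncate_cranial=True)
        ])
    ])
    generate_cohort(spec, tmp_path, dialect="dicom")
    return scan_directory(tmp_path, dialect="dicom")


def test_load_volume_applies_hu_rescale(tmp_path):
    """Stored value 1024 with slope 1, intercept -1024 reads back as 0 HU."""
    scan = _tiny_dicom_cohort(tmp_path)
    series = scan.studies[0].series[0]
    ds = pydicom.dcmread(series.file_paths[0])
    assert float(ds.RescaleIntercept) == -1024.0
    vol = load_volume(series)
    raw = ds.pixel_array.astype(float).T
    assert np.allclose(vol.voxels[:, :, 0], raw - 1024.0)


def test_load_volume_sort_invariance(tmp_path):
    """Shuffled file order yields the identical volume."""
    scan = _tiny_dicom_cohort(tmp_path, n_slices=5)
    series = scan.studies[0].series[0]
    ref = load_volume(series)
    shuffled = list(series.file_paths)
    shuffled.reverse()
    series.file_paths = shuffled
    assert np.array_equal(load_volume(series).voxels, ref.voxels)
    assert load_volume(series).geometry == ref.geometry


def test_load_volume_inconsistent_geometry_is_corrupt(tmp_path):
    scan = _tiny_dicom_cohort(tmp_path)
    series = scan.studies[0].series[0]
    ds = pydicom.dcmread(series.file_paths[1])
    ds.PixelSpacing = [3.0, 3.0]
    ds.save_as(series.file_paths[1], enforce_file_format=True)
    with pytest.raises(CorruptSeriesError):
        load_volume(series)


def test_nifti_load_round_trips_geometry(small_cohort):
    """Loading a written series reproduces spacing and HU content."""
    out, bundle = small_cohort
    scan = scan_directory(out, dialect="nifti_sidecar")
    series = next(
        se for st in scan.studies for se in st.series
        if se.orientation_class == "axial" and se.slice_count >= 20
    )
    vol = load_volume(series)
    assert vol.geometry.spacing == (1.5, 1.5, 1.5)
    assert vol.geometry.size == (64, 64, 60)
    vol.validate_hu_range()
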