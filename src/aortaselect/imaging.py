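"""Series discovery, grouping, orientation classification, and volume loading.

Supports two on-disk dialects:

``dicom``
    DICOM Part-10, one file per slice, grouped by
    ``(StudyInstanceUID, SeriesInstanceUID)``.
``nifti_sidecar``
    One NIfTI-1 volume per series with a JSON sidecar carrying the same
    acquisition metadata (study/series identifiers, direction cosines, slice
    positions, reported slice thickness).

Unreadable or inconsistent files never abort a scan: they are recorded in a
skip log with a reason, mirroring how heterogeneous clinical archives are
curated in practice (corrupted files are discarded, not fatal).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import nibabel as nib
import numpy as np
import pydicom

from .geometry import GeometryError, ImageVolume, VolumeGeometry

__all__ = [
    "SeriesRecord",
    "StudyRecord",
    "SkipRecord",
    "CohortScan",
    "CorruptSeriesError",
    "scan_directory",
    "classify_orientation",
    "compute_slice_spacing",
    "load_volume",
    "is_volumetric",
]

logger = logging.getLogger(__name__)

ORIENTATION_CLASSES = ("axial", "coronal", "sagittal", "oblique", "unknown")

#: LPS patient axes checked, in order, against the slice normal.
_AXIS_BY_CLASS = (("axial", np.array([0.0, 0.0, 1.0])),
                  ("coronal", np.array([0.0, 1.0, 0.0])),
                  ("sagittal", np.array([1.0, 0.0, 0.0])))


class CorruptSeriesError(RuntimeError):
    """A series whose files are unreadable or geometrically inconsistent."""


@dataclass
class SkipRecord:
    path: str
    reason: str


@dataclass
class SeriesRecord:
    """One reconstruction/acquisition within a study."""

    series_uid: str
    study_uid: str
    patient_id: str
    modality: str
    file_paths: list[Path]
    slice_count: int
    orientation_class: str = "unknown"
    reported_slice_thickness: Optional[float] = None
    computed_slice_spacing: Optional[float] = None
    spacing_uniform: Optional[bool] = None
    dialect: str = "dicom"


@dataclass
class StudyRecord:
    """One imaging encounter: a group of series sharing a study identifier."""

    study_uid: str
    patient_id: str
    series: list[SeriesRecord]


@dataclass
class CohortScan:
    """Result of scanning a directory tree: studies found plus skip log."""

    studies: list[StudyRecord]
    skipped: list[SkipRecord] = field(default_factory=list)

    @property
    def n_series(self) -> int:
        return sum(len(s.series) for s in self.studies)

    def write_skip_log(self, path: Path | str) -> None:
        """JSON-lines skip log: one ``{"path": ..., "reason": ...}`` per entry."""
        with open(path, "w") as fh:
            for rec in self.skipped:
                fh.write(json.dumps({"path": rec.path, "reason": rec.reason}) + "\n")


def classify_orientation(
    row_cosines: Iterable[float],
    col_cosines: Iterable[float],
    tolerance_deg: float = 10.0,
) -> str:
    """Classify the slice plane from row/column direction cosines.

    The slice normal is the cross product of the row and column cosines; the
    class is ``axial``/``coronal``/``sagittal`` when the absolute angle between
    the normal and the corresponding LPS axis (+z/+y/+x) is within
    ``tolerance_deg``, else ``oblique``.  Missing or non-unit cosines yield
    ``unknown`` (such series later fail the axial filter).
    """
    try:
        row = np.asarray(list(row_cosines), dtype=float)
        col = np.asarray(list(col_cosines), dtype=float)
    except (TypeError, ValueError):
        return "unknown"
    if row.shape != (3,) or col.shape != (3,):
        return "unknown"
    if not np.isfinite(row).all() or not np.isfinite(col).all():
        return "unknown"
    if abs(np.linalg.norm(row) - 1.0) > 1e-3 or abs(np.linalg.norm(col) - 1.0) > 1e-3:
        return "unknown"
    normal = np.cross(row, col)
    nn = np.linalg.norm(normal)
    if nn < 1e-6:
        return "unknown"
    normal = normal / nn
    for cls, axis in _AXIS_BY_CLASS:
        angle = np.degrees(np.arccos(np.clip(abs(float(normal @ axis)), 0.0, 1.0)))
        if angle <= tolerance_deg:
            return cls
    return "oblique"


def compute_slice_spacing(
    slice_positions: Iterable[float],
) -> Optional[tuple[float, bool]]:
    """Median adjacent gap along the slice normal, plus a uniformity flag.

    ``uniform`` is true iff every adjacent gap is within 10% of the median
    gap.  Returns ``None`` for fewer than two positions (callers fall back to
    the reported slice-thickness tag).
    """
    pos = np.asarray(sorted(float(p) for p in slice_positions))
    if pos.size < 2:
        return None
    gaps = np.abs(np.diff(pos))
    med = float(np.median(gaps))
    if med <= 0:
        return None
    uniform = bool(np.all(np.abs(gaps - med) <= 0.10 * med))
    return med, uniform


def is_volumetric(series: SeriesRecord, min_slices: int = 20) -> bool:
    """True for a 3D CT acquisition: at least ``min_slices`` slices.

    Single-slice scouts/localizers and short secondary captures fail this;
    so do non-CT modalities.
    """
    return series.slice_count >= min_slices and series.modality.upper() == "CT"


# ---------------------------------------------------------------------------
# directory scanning
# ---------------------------------------------------------------------------


def scan_directory(
    root: Path | str, dialect: str = "dicom", tolerance_deg: float = 10.0
) -> CohortScan:
    """Discover and group all readable CT series under ``root``.

    Every readable series appears in exactly one :class:`StudyRecord`;
    unreadable or corrupt files go to the skip log with a reason and never
    raise.  An empty root yields an empty cohort plus a warning.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(root)
    if dialect == "dicom":
        scan = _scan_dicom(root, tolerance_deg)
    elif dialect == "nifti_sidecar":
        scan = _scan_nifti(root, tolerance_deg)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not scan.studies:
        warnings.warn(f"no readable series found under {root}", stacklevel=2)
    return scan


def _scan_dicom(root: Path, tolerance_deg: float) -> CohortScan:
    groups: dict[tuple[str, str], list[tuple[Path, pydicom.Dataset]]] = {}
    skipped: list[SkipRecord] = []
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        if "ground_truth" in path.parts:
            continue
        if path.suffix.lower() in {".json", ".nii", ".gz", ".txt", ".csv"}:
            continue
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except Exception:
            skipped.append(SkipRecord(str(path), "unreadable_dicom"))
            continue
        study = str(getattr(ds, "StudyInstanceUID", "") or "")
        series = str(getattr(ds, "SeriesInstanceUID", "") or "")
        if not study or not series:
            skipped.append(SkipRecord(str(path), "missing_identifiers"))
            continue
        if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
            skipped.append(SkipRecord(str(path), "multiframe_unsupported"))
            continue
        groups.setdefault((study, series), []).append((path, ds))

    studies: dict[str, StudyRecord] = {}
    for (study_uid, series_uid), items in sorted(groups.items()):
        rec = _series_from_dicom(study_uid, series_uid, items, tolerance_deg)
        st = studies.setdefault(
            study_uid, StudyRecord(study_uid, rec.patient_id, [])
        )
        st.series.append(rec)
    return CohortScan(list(studies.values()), skipped)


def _slice_sort_positions(
    items: list[tuple[Path, pydicom.Dataset]]
) -> Optional[list[float]]:
    """Projection of each slice's position onto the slice normal, or None."""
    ds0 = items[0][1]
    iop = getattr(ds0, "ImageOrientationPatient", None)
    if iop is None or len(iop) != 6:
        return None
    row = np.asarray(iop[:3], dtype=float)
    col = np.asarray(iop[3:], dtype=float)
    normal = np.cross(row, col)
    out = []
    for _, ds in items:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None or len(ipp) != 3:
            return None
        out.append(float(np.asarray(ipp, dtype=float) @ normal))
    return out


def _series_from_dicom(
    study_uid: str,
    series_uid: str,
    items: list[tuple[Path, pydicom.Dataset]],
    tolerance_deg: float,
) -> SeriesRecord:
    positions = _slice_sort_positions(items)
    if positions is not None:
        order = np.argsort(positions)
        items = [items[i] for i in order]
        positions = [positions[i] for i in order]
    ds0 = items[0][1]
    iop = getattr(ds0, "ImageOrientationPatient", None)
    if iop is not None and len(iop) == 6:
        orientation = classify_orientation(iop[:3], iop[3:], tolerance_deg)
    else:
        orientation = "unknown"
    thickness = getattr(ds0, "SliceThickness", None)
    thickness = float(thickness) if thickness not in (None, "") else None
    spacing_info = compute_slice_spacing(positions) if positions else None
    return SeriesRecord(
        series_uid=series_uid,
        study_uid=study_uid,
        patient_id=str(getattr(ds0, "PatientID", "") or ""),
        modality=str(getattr(ds0, "Modality", "") or ""),
        file_paths=[p for p, _ in items],
        slice_count=len(items),
        orientation_class=orientation,
        reported_slice_thickness=thickness,
        computed_slice_spacing=spacing_info[0] if spacing_info else None,
        spacing_uniform=spacing_info[1] if spacing_info else None,
        dialect="dicom",
    )


def _scan_nifti(root: Path, tolerance_deg: float) -> CohortScan:
    studies: dict[str, StudyRecord] = {}
    skipped: list[SkipRecord] = []
    for path in sorted(root.rglob("*.nii")):
        if "ground_truth" in path.parts:
            continue
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            skipped.append(SkipRecord(str(path), "missing_sidecar"))
            continue
        try:
            meta = json.loads(sidecar.read_text())
            img = nib.load(path)
            n_slices = int(img.shape[2]) if len(img.shape) >= 3 else 1
        except Exception:
            skipped.append(SkipRecord(str(path), "unreadable_nifti"))
            continue
        study_uid = str(meta.get("study_uid", ""))
        series_uid = str(meta.get("series_uid", ""))
        if not study_uid or not series_uid:
            skipped.append(SkipRecord(str(path), "missing_identifiers"))
            continue
        orientation = classify_orientation(
            meta.get("row_cosines", ()), meta.get("col_cosines", ()), tolerance_deg
        )
        positions = meta.get("slice_positions")
        spacing_info = compute_slice_spacing(positions) if positions else None
        thickness = meta.get("slice_thickness")
        rec = SeriesRecord(
            series_uid=series_uid,
            study_uid=study_uid,
            patient_id=str(meta.get("patient_id", "")),
            modality=str(meta.get("modality", "CT")),
            file_paths=[path],
            slice_count=n_slices,
            orientation_class=orientation,
            reported_slice_thickness=float(thickness) if thickness else None,
            computed_slice_spacing=spacing_info[0] if spacing_info else None,
            spacing_uniform=spacing_info[1] if spacing_info else None,
            dialect="nifti_sidecar",
        )
        st = studies.setdefault(
            study_uid, StudyRecord(study_uid, rec.patient_id, [])
        )
        st.series.append(rec)
    return CohortScan(list(studies.values()), skipped)


# ---------------------------------------------------------------------------
# volume loading
# ---------------------------------------------------------------------------


def load_volume(series: SeriesRecord) -> ImageVolume:
    """Load a series into an HU :class:`ImageVolume`.

    DICOM slices are sorted by position along the slice normal and rescaled
    with the (slope, intercept) tags; NIfTI volumes are assumed to already be
    in HU.  Inconsistent in-plane geometry across slices raises
    :class:`CorruptSeriesError` (the pipeline records such a series as a
    corrupt-series skip).
    """
    if series.dialect == "nifti_sidecar":
        return _load_nifti(series)
    return _load_dicom(series)


def _load_dicom(series: SeriesRecord) -> ImageVolume:
    slices = []
    for path in series.file_paths:
        try:
            slices.append((path, pydicom.dcmread(path)))
        except Exception as exc:
            raise CorruptSeriesError(f"unreadable slice {path}") from exc
    positions = _slice_sort_positions(slices)
    if positions is None:
        raise CorruptSeriesError("missing position/orientation tags")
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = sorted(positions)

    ds0 = slices[0][1]
    iop = np.asarray(ds0.ImageOrientationPatient, dtype=float)
    pix = np.asarray(ds0.PixelSpacing, dtype=float)
    shape = (int(ds0.Rows), int(ds0.Columns))
    for _, ds in slices[1:]:
        if (int(ds.Rows), int(ds.Columns)) != shape:
            raise CorruptSeriesError("inconsistent matrix size across slices")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), pix, atol=1e-4):
            raise CorruptSeriesError("inconsistent pixel spacing across slices")
        if not np.allclose(
            np.asarray(ds.ImageOrientationPatient, dtype=float), iop, atol=1e-4
        ):
            raise CorruptSeriesError("inconsistent orientation across slices")

    row = iop[:3] / np.linalg.norm(iop[:3])
    col = iop[3:] / np.linalg.norm(iop[3:])
    normal = np.cross(row, col)

    if len(slices) >= 2:
        spacing_info = compute_slice_spacing(positions)
        slice_spacing = spacing_info[0] if spacing_info else 1.0
    else:
        slice_spacing = series.reported_slice_thickness or 1.0

    # voxel axis 0 runs along the row direction (column index in the DICOM
    # frame), axis 1 along the column direction, axis 2 along the normal
    planes = []
    for _, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(ds.pixel_array.astype(np.float32).T * slope + intercept)
    voxels = np.stack(planes, axis=2)

    origin = np.asarray(slices[0][1].ImagePositionPatient, dtype=float)
    direction = np.column_stack([row, col, normal])
    # DICOM PixelSpacing is (row spacing, column spacing) = (between rows,
    # between columns); axis 0 advances along the row direction so its step
    # is the column spacing
    geometry = VolumeGeometry(
        origin=tuple(origin),
        spacing=(float(pix[1]), float(pix[0]), float(slice_spacing)),
        direction=direction,
        size=voxels.shape,
    )
    return ImageVolume(geometry, voxels, provenance=series.series_uid)


def _load_nifti(series: SeriesRecord) -> ImageVolume:
    path = series.file_paths[0]
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    affine = img.affine.copy()
    # NIfTI affines are RAS; flip the first two rows to the DICOM LPS frame
    affine[0, :] *= -1.0
    affine[1, :] *= -1.0
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    direction = lin / spacing
    geometry = VolumeGeometry(
        origin=tuple(affine[:3, 3]),
        spacing=tuple(spacing),
        direction=direction,
        size=data.shape,
    )
    return ImageVolume(geometry, data, provenance=series.series_uid)
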