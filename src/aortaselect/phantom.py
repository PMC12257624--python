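"""Synthetic chest-CT phantoms with ground-truth masks and expected outcomes.

The phantom is schematic — a soft-tissue body cylinder, two lung ellipsoids,
a candy-cane aortic tube (ascending limb, arch half-torus, descending limb),
and an optional brachiocephalic branch — because the selection pipeline
consumes only masks and intensities, not anatomy.  Every inclusion and
exclusion category the pipeline must distinguish can be emulated:

* arterial vs non-contrast blood pool (lumen HU 320 vs 45);
* thrombosed-dissection lumens: a contiguous angular wedge of the aortic
  cross-section at ~60 HU, whose fraction controls whether the median HU
  drops below the contrast threshold;
* coronal reformats, single-slice scouts, thick (5 mm) reconstructions;
* fields of view that truncate the aorta cranially or laterally;
* abdominal-style series without lungs, or without the brachiocephalic trunk.

Tissue HU constants are clinically plausible round numbers placed
unambiguously on the correct side of the 150 HU contrast threshold; the
arterial default of 320 HU matches the typical cohort-level median aortic
attenuation of arterial-phase studies.  Additive Gaussian noise is seeded and
fully reproducible; ground-truth masks are exact geometry, noise-free.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .geometry import ImageVolume, VolumeGeometry
from .segmentation import LABELS, LabelMask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "StudySpec",
    "CohortSpec",
    "PhantomSpecError",
    "generate_phantom",
    "generate_cohort",
    "standard_cohort",
    "load_ground_truth_bundle",
    "load_ground_truth_masks",
]

# tissue intensities (HU)
AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
LUNG_HU = -800.0
THROMBUS_HU = 60.0
ARTERIAL_HU = 320.0
NONCONTRAST_HU = 45.0

AORTA_RADIUS_MM = 7.0
BRACHIO_RADIUS_MM = 6.0


class PhantomSpecError(ValueError):
    """Geometrically impossible or invalid phantom parameters."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic series."""

    series_uid: str = "series-0"
    study_uid: str = "study-0"
    patient_id: str = "patient-0"
    grid_size: tuple[int, int] = (64, 64)   # in-plane voxels
    n_slices: int = 60
    in_plane_spacing: float = 1.5           # mm
    slice_spacing: float = 1.5              # mm
    orientation: str = "axial"              # "axial" | "coronal"
    aorta_lumen_hu: float = ARTERIAL_HU
    thrombus_fraction: float = 0.0
    thrombus_hu: float = THROMBUS_HU
    truncate_cranial: bool = False
    truncate_lateral: bool = False
    include_lungs: bool = True
    include_brachiocephalic: bool = True
    scout: bool = False
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.thrombus_fraction <= 1.0):
            raise PhantomSpecError("thrombus_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if self.in_plane_spacing <= 0 or self.slice_spacing <= 0:
            raise PhantomSpecError("spacings must be positive")


@dataclass
class GroundTruth:
    """Exact masks plus the outcome the pipeline is expected to produce."""

    series_uid: str
    masks: dict[str, LabelMask]
    expected_outcome: str  # "selected_candidate" or an exclusion step name
    expected_median_hu: Optional[float]
    median_tolerance: Optional[float]


@dataclass
class StudySpec:
    study_uid: str
    patient_id: str
    series: list[PhantomSpec]

    def __post_init__(self) -> None:
        if not self.series:
            raise PhantomSpecError("every study needs at least one series")


@dataclass
class CohortSpec:
    studies: list[StudySpec]
    master_seed: int = 0


# ---------------------------------------------------------------------------
# geometry of the schematic anatomy (mm, in a canonical LPS frame where the
# caudal-most slice sits at z = 0)
# ---------------------------------------------------------------------------

_ASC_CENTER = (-9.0, -12.0)   # ascending aorta: right-anterior
_DESC_CENTER = (9.0, 16.0)    # descending aorta: left-posterior, near spine
_Z_ARCH = 52.0                # cylinders end / arch torus begins
_Z_ASC_BOTTOM = 25.0          # ascending limb starts at heart level
_LUNG_CENTERS = ((-24.0, 2.0), (24.0, 2.0))
_LUNG_SEMI = (13.0, 24.0, 33.0)
_LUNG_ZC = 42.0
_BODY_SEMI = (45.0, 38.0)
_BODY_CENTER = (0.0, 2.0)
_BRACHIO_XY = (-6.0, -16.0)  # anterior to the arch plane, like the innominate origin
_BRACHIO_Z = (62.0, 82.0)
_SCOUT_Z = 40.0               # single mid-thorax slice for scouts


def _phantom_geometry(spec: PhantomSpec) -> tuple[VolumeGeometry, np.ndarray]:
    """Grid geometry plus the anatomy-frame coordinates of voxel centers.

    Truncation flags shift the anatomy relative to the field of view so the
    aorta reaches the stated boundary; this is expressed by offsetting the
    anatomy-frame coordinates, keeping the grid itself fixed.
    """
    nx, ny = spec.grid_size
    nz = 1 if spec.scout else spec.n_slices
    sp = (spec.in_plane_spacing, spec.in_plane_spacing, spec.slice_spacing)
    origin_xy = (-(nx - 1) / 2.0 * sp[0], -(ny - 1) / 2.0 * sp[1])
    origin_z = _SCOUT_Z if spec.scout else 0.0

    if spec.orientation == "axial":
        direction = np.eye(3)
    elif spec.orientation == "coronal":
        # row along +x, column along -z => slice normal +y
        direction = np.column_stack(
            [[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]
        )
    else:
        raise PhantomSpecError(f"unsupported orientation {spec.orientation!r}")

    geom = VolumeGeometry(
        origin=(origin_xy[0], origin_xy[1], origin_z)
        if spec.orientation == "axial"
        else (origin_xy[0], 40.0, 80.0),
        spacing=sp,
        direction=direction,
        size=(nx, ny, nz),
    )

    pts = geom.voxel_centers()  # (nx, ny, nz, 3) in patient LPS mm
    # anatomy offsets implementing truncation
    shift = np.zeros(3)
    if spec.truncate_lateral:
        # push the descending aorta across the patient-left FOV boundary:
        # the top-of-FOV x must land just inside the descending tube
        x_max = pts[..., 0].max()
        shift[0] = (_DESC_CENTER[0] + AORTA_RADIUS_MM) - 0.6 - x_max
    if spec.truncate_cranial:
        # raise the anatomy so the arch reaches the most-superior slice
        z_max = pts[..., 2].max()
        arch_top = _Z_ARCH + _arch_major_radius() + AORTA_RADIUS_MM
        shift[2] = arch_top - 0.6 - z_max
    anat = pts + shift  # anatomy-frame coordinates of each voxel center
    return geom, anat


def _arch_major_radius() -> float:
    ca = np.asarray(_ASC_CENTER)
    cd = np.asarray(_DESC_CENTER)
    return float(np.linalg.norm(cd - ca) / 2.0)


def _aorta_mask_and_angle(anat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean aorta mask plus a per-voxel cross-section angle in [0, 2pi).

    The angle parameterizes position around the local vessel centerline and
    is used to carve a contiguous mural-thrombus wedge.
    """
    x, y, z = anat[..., 0], anat[..., 1], anat[..., 2]
    r = AORTA_RADIUS_MM
    theta = np.zeros(x.shape)
    mask = np.zeros(x.shape, dtype=bool)

    for (cx, cy), zlo in ((_ASC_CENTER, _Z_ASC_BOTTOM), (_DESC_CENTER, None)):
        dx, dy = x - cx, y - cy
        inside = (dx * dx + dy * dy <= r * r) & (z <= _Z_ARCH)
        if zlo is not None:
            inside &= z >= zlo
        mask |= inside
        theta = np.where(inside & (theta == 0), np.arctan2(dy, dx) % (2 * np.pi), theta)

    # arch: half torus in the vertical plane through both cylinder axes
    ca = np.asarray(_ASC_CENTER)
    cd = np.asarray(_DESC_CENTER)
    mid = (ca + cd) / 2.0
    u = (cd - ca) / np.linalg.norm(cd - ca)
    big_r = _arch_major_radius()
    a = (x - mid[0]) * u[0] + (y - mid[1]) * u[1]          # along the cylinder line
    b = -(x - mid[0]) * u[1] + (y - mid[1]) * u[0]          # off the arch plane
    h = z - _Z_ARCH
    rho = np.hypot(a, h)
    tube = np.sqrt((rho - big_r) ** 2 + b * b)
    arch = (tube <= r) & (h >= 0)
    mask |= arch
    theta = np.where(arch & (theta == 0), np.arctan2(b, rho - big_r) % (2 * np.pi), theta)
    return mask, theta


def _masks_from_spec(
    spec: PhantomSpec, geom: VolumeGeometry, anat: np.ndarray
) -> tuple[dict[str, LabelMask], np.ndarray, np.ndarray]:
    x, y, z = anat[..., 0], anat[..., 1], anat[..., 2]

    aorta, theta = _aorta_mask_and_angle(anat)

    lungs = np.zeros(aorta.shape, dtype=bool)
    if spec.include_lungs:
        for cx, cy in _LUNG_CENTERS:
            lungs |= (
                ((x - cx) / _LUNG_SEMI[0]) ** 2
                + ((y - cy) / _LUNG_SEMI[1]) ** 2
                + ((z - _LUNG_ZC) / _LUNG_SEMI[2]) ** 2
            ) <= 1.0
        lungs &= ~aorta

    brachio = np.zeros(aorta.shape, dtype=bool)
    if spec.include_brachiocephalic:
        bx, by = _BRACHIO_XY
        brachio = (
            (np.hypot(x - bx, y - by) <= BRACHIO_RADIUS_MM)
            & (z >= _BRACHIO_Z[0])
            & (z <= _BRACHIO_Z[1])
            & ~aorta
        )

    masks = {
        "aorta": LabelMask("aorta", geom, aorta),
        "lungs_composite": LabelMask("lungs_composite", geom, lungs),
        "brachiocephalic_trunk": LabelMask("brachiocephalic_trunk", geom, brachio),
    }
    return masks, theta, (x, y, z)


def _thrombus_selection(
    aorta: np.ndarray, theta: np.ndarray, fraction: float
) -> np.ndarray:
    """Contiguous angular wedge of exactly round(fraction * N) aorta voxels."""
    sel = np.zeros(aorta.shape, dtype=bool)
    if fraction <= 0:
        return sel
    flat_idx = np.flatnonzero(aorta.ravel())
    n_th = int(round(fraction * flat_idx.size))
    if n_th == 0:
        return sel
    order = np.argsort(theta.ravel()[flat_idx], kind="stable")
    chosen = flat_idx[order[:n_th]]
    sel.ravel()[chosen] = True
    return sel


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Build one synthetic series and its ground truth.

    Raises :class:`PhantomSpecError` when the aorta reaches a checked FOV
    boundary without the matching truncation flag (a geometrically
    inconsistent spec).
    """
    geom, anat = _phantom_geometry(spec)
    masks, theta, (x, y, z) = _masks_from_spec(spec, geom, anat)
    aorta = masks["aorta"].voxels

    hu = np.full(aorta.shape, AIR_HU, dtype=np.float32)
    body = (
        ((x - _BODY_CENTER[0]) / _BODY_SEMI[0]) ** 2
        + ((y - _BODY_CENTER[1]) / _BODY_SEMI[1]) ** 2
    ) <= 1.0
    hu[body] = SOFT_TISSUE_HU
    hu[masks["lungs_composite"].voxels] = LUNG_HU
    hu[aorta] = spec.aorta_lumen_hu
    thrombus = _thrombus_selection(aorta, theta, spec.thrombus_fraction)
    hu[thrombus] = spec.thrombus_hu
    hu[masks["brachiocephalic_trunk"].voxels] = spec.aorta_lumen_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    volume = ImageVolume(geom, hu, provenance=spec.series_uid)

    _check_geometric_consistency(spec, masks["aorta"])
    truth = GroundTruth(
        series_uid=spec.series_uid,
        masks=masks,
        expected_outcome=_expected_outcome(spec),
        expected_median_hu=_expected_median(spec),
        median_tolerance=_median_tolerance(spec, int(aorta.sum())),
    )
    return volume, truth


def _check_geometric_consistency(spec: PhantomSpec, aorta: LabelMask) -> None:
    if spec.orientation != "axial" or spec.scout:
        return
    m = aorta.voxels
    if not m.any():
        raise PhantomSpecError("phantom produced an empty aorta mask")
    touches_cranial = bool(m[:, :, -1].any())
    touches_lateral = bool(m[0, :, :].any() or m[-1, :, :].any())
    if touches_cranial and not spec.truncate_cranial:
        raise PhantomSpecError("aorta exits the FOV cranially without the flag")
    if touches_lateral and not spec.truncate_lateral:
        raise PhantomSpecError("aorta exits the FOV laterally without the flag")
    if spec.truncate_cranial and not touches_cranial:
        raise PhantomSpecError("truncate_cranial set but the aorta stays interior")
    if spec.truncate_lateral and not touches_lateral:
        raise PhantomSpecError("truncate_lateral set but the aorta stays interior")


def _expected_median(spec: PhantomSpec) -> Optional[float]:
    if spec.thrombus_fraction > 0.5:
        return spec.thrombus_hu
    return spec.aorta_lumen_hu


def _median_tolerance(spec: PhantomSpec, n_voxels: int) -> float:
    # sampling error of a median of n noisy voxels, plus a quantile-shift
    # allowance when a thrombus wedge puts the median near a population edge
    n = max(n_voxels, 1)
    tol = 5.0 * 1.2533 * spec.noise_sd / np.sqrt(n) + 0.5
    if 0.0 < spec.thrombus_fraction < 1.0:
        tol += 3.0 * spec.noise_sd + 1.0
    return float(tol)


def _expected_outcome(
    spec: PhantomSpec, hu_threshold: float = 150.0, max_thickness: float = 3.0,
    min_slices: int = 20,
) -> str:
    """First cascade step the spec parameters fail, by construction."""
    n_slices = 1 if spec.scout else spec.n_slices
    if spec.orientation != "axial" or n_slices < min_slices:
        return "axial3d"
    if not spec.include_lungs or not spec.include_brachiocephalic:
        return "labels"
    if not (_expected_median(spec) or 0.0) > hu_threshold:
        return "contrast"
    if spec.truncate_cranial or spec.truncate_lateral:
        return "complete_aorta"
    if spec.slice_spacing > max_thickness:
        return "thickness"
    return "selected_candidate"


# ---------------------------------------------------------------------------
# cohort generation and serialization
# ---------------------------------------------------------------------------


def _derived_seed(master_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def standard_cohort(
    master_seed: int = 0,
    n_good: int = 30,
    n_paired: int = 10,
    n_coronal: int = 4,
    n_scout: int = 4,
    n_nolungs: int = 4,
    n_nobrachio: int = 2,
    n_noncontrast: int = 4,
    n_trunc_cranial: int = 4,
    n_trunc_lateral: int = 2,
    n_thick: int = 4,
    n_thrombus_low: int = 2,
    n_thrombus_high: int = 2,
) -> CohortSpec:
    """A mixed cohort spanning every inclusion/exclusion category.

    ``n_paired`` studies carry a non-contrast plus an arterial series (the
    arterial one must win); ``n_thrombus_low/high`` carry dissection lumens
    with thrombus fractions 0.25 (still arterial-median) and 0.75 (median
    collapses to thrombus HU, the classic false-exclusion failure mode).
    The category counts are realized exactly, not probabilistically.
    """
    studies: list[StudySpec] = []
    counter = 0

    def add(series_kwargs_list: list[dict]) -> None:
        nonlocal counter
        study_uid = f"study-{counter:04d}"
        patient_id = f"patient-{counter:04d}"
        series = []
        for j, kwargs in enumerate(series_kwargs_list):
            series_uid = f"{study_uid}-s{j}"
            series.append(
                PhantomSpec(
                    series_uid=series_uid,
                    study_uid=study_uid,
                    patient_id=patient_id,
                    seed=_derived_seed(master_seed, series_uid),
                    **kwargs,
                )
            )
        studies.append(StudySpec(study_uid, patient_id, series))
        counter += 1

    for _ in range(n_good):
        add([{}])
    for _ in range(n_paired):
        add([{"aorta_lumen_hu": NONCONTRAST_HU}, {}])
    for _ in range(n_coronal):
        add([{"orientation": "coronal"}])
    for _ in range(n_scout):
        add([{"scout": True}])
    for _ in range(n_nolungs):
        add([{"include_lungs": False}])
    for _ in range(n_nobrachio):
        add([{"include_brachiocephalic": False}])
    for _ in range(n_noncontrast):
        add([{"aorta_lumen_hu": NONCONTRAST_HU}])
    for _ in range(n_trunc_cranial):
        add([{"truncate_cranial": True}])
    for _ in range(n_trunc_lateral):
        add([{"truncate_lateral": True}])
    for _ in range(n_thick):
        add([{"slice_spacing": 5.0, "n_slices": 30}])
    for _ in range(n_thrombus_low):
        add([{"thrombus_fraction": 0.25}])
    for _ in range(n_thrombus_high):
        add([{"thrombus_fraction": 0.75}])
    return CohortSpec(studies, master_seed)


def generate_cohort(
    spec: CohortSpec, out_dir: Path | str, dialect: str = "nifti_sidecar"
) -> dict[str, GroundTruth]:
    """Write every series of the cohort to disk plus its ground truth bundle.

    Returns the in-memory ground-truth bundle keyed by the on-disk series
    identifier (for the DICOM dialect this is a deterministic UID derived
    from the logical series name, so the oracle backend and re-scanned
    records agree).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_dir = out_dir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)

    bundle: dict[str, GroundTruth] = {}
    expected: dict[str, dict] = {}
    for study in spec.studies:
        for pspec in study.series:
            volume, truth = generate_phantom(pspec)
            if dialect == "nifti_sidecar":
                disk_uid = pspec.series_uid
                _write_nifti_series(out_dir, pspec, volume)
            elif dialect == "dicom":
                disk_uid = _dicom_uid(pspec.series_uid)
                _write_dicom_series(out_dir, pspec, volume, disk_uid)
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            truth = replace(truth, series_uid=disk_uid)
            bundle[disk_uid] = truth
            _write_truth_masks(truth_dir, disk_uid, truth)
            expected[disk_uid] = {
                "logical_series_uid": pspec.series_uid,
                "study_uid": pspec.study_uid,
                "expected_outcome": truth.expected_outcome,
                "expected_median_hu": truth.expected_median_hu,
                "median_tolerance": truth.median_tolerance,
            }
    (truth_dir / "expected.json").write_text(
        json.dumps(expected, indent=2, sort_keys=True) + "\n"
    )
    return bundle


def _lps_to_ras_affine(geom: VolumeGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = geom.index_to_patient_matrix
    affine[:3, 3] = geom.origin
    affine[0, :] *= -1.0
    affine[1, :] *= -1.0
    return affine


def _write_nifti_series(out_dir: Path, spec: PhantomSpec, volume: ImageVolume) -> None:
    study_dir = out_dir / spec.study_uid
    study_dir.mkdir(exist_ok=True)
    path = study_dir / f"{spec.series_uid}.nii"
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32), _lps_to_ras_affine(volume.geometry)
    )
    nib.save(img, path)
    geom = volume.geometry
    normal = geom.direction[:, 2]
    positions = [
        float(np.asarray(geom.voxel_to_patient([0.0, 0.0, float(k)])) @ normal)
        for k in range(geom.size[2])
    ]
    sidecar = {
        "study_uid": spec.study_uid,
        "series_uid": spec.series_uid,
        "patient_id": spec.patient_id,
        "modality": "CT",
        "row_cosines": [float(v) for v in geom.direction[:, 0]],
        "col_cosines": [float(v) for v in geom.direction[:, 1]],
        "slice_positions": positions,
        "slice_thickness": spec.slice_spacing,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _dicom_uid(name: str) -> str:
    digest = hashlib.sha256(name.encode()).digest()
    return "2.25." + str(int.from_bytes(digest[:12], "big"))


def _write_dicom_series(
    out_dir: Path, spec: PhantomSpec, volume: ImageVolume, series_uid: str
) -> None:
    geom = volume.geometry
    study_uid = _dicom_uid(spec.study_uid)
    series_dir = out_dir / spec.study_uid / spec.series_uid
    series_dir.mkdir(parents=True, exist_ok=True)
    stored = np.clip(np.rint(volume.voxels + 1024.0), 0, 65535).astype(np.uint16)
    for k in range(geom.size[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = _dicom_uid(f"{spec.series_uid}/{k}")
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = spec.patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [
            float(v) for v in np.concatenate([geom.direction[:, 0], geom.direction[:, 1]])
        ]
        ds.ImagePositionPatient = [
            float(v) for v in geom.voxel_to_patient([0.0, 0.0, float(k)])
        ]
        # PixelSpacing is (row spacing, column spacing); voxel axis 0 runs
        # along the row direction, so its step is the column spacing
        ds.PixelSpacing = [float(geom.spacing[1]), float(geom.spacing[0])]
        ds.SliceThickness = float(spec.slice_spacing)
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = int(geom.size[1]), int(geom.size[0])
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        ds.save_as(series_dir / f"slice_{k:04d}.dcm", enforce_file_format=True)


def _write_truth_masks(truth_dir: Path, disk_uid: str, truth: GroundTruth) -> None:
    safe = hashlib.sha256(disk_uid.encode()).hexdigest()[:16]
    label_img = np.zeros(truth.masks["aorta"].geometry.size, dtype=np.uint8)
    for i, label in enumerate(LABELS, start=1):
        label_img[truth.masks[label].voxels] = i
    img = nib.Nifti1Image(
        label_img, _lps_to_ras_affine(truth.masks["aorta"].geometry)
    )
    nib.save(img, truth_dir / f"{safe}_labels.nii")
    (truth_dir / f"{safe}_uid.json").write_text(
        json.dumps({"series_uid": disk_uid}) + "\n"
    )


def load_ground_truth_masks(
    truth_dir: Path, series_uid: str
) -> Optional[dict[str, LabelMask]]:
    """Read one series' ground-truth masks written by :func:`generate_cohort`."""
    safe = hashlib.sha256(series_uid.encode()).hexdigest()[:16]
    path = truth_dir / f"{safe}_labels.nii"
    if not path.exists():
        return None
    img = nib.load(path)
    affine = img.affine.copy()
    affine[0, :] *= -1.0
    affine[1, :] *= -1.0
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    geom = VolumeGeometry(
        origin=tuple(affine[:3, 3]),
        spacing=tuple(spacing),
        direction=lin / spacing,
        size=img.shape[:3],
    )
    data = np.asarray(img.dataobj)
    return {
        label: LabelMask(label, geom, data == i)
        for i, label in enumerate(LABELS, start=1)
    }


def load_ground_truth_bundle(out_dir: Path | str) -> dict[str, dict]:
    """Read the expected-outcome records for a cohort directory."""
    path = Path(out_dir) / "ground_truth" / "expected.json"
    return json.loads(path.read_text())
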