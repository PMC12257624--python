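"""Pluggable segmentation backends and mask-grid resampling.

The selection pipeline needs three label masks per volume: the aorta, the
composite lungs (union of all lobes/sides), and the brachiocephalic trunk
(whose visibility implies the top of the aortic arch is in the field of
view).  Segmentation itself is an off-the-shelf capability, not this
package's contribution, so it sits behind a uniform contract:

* :class:`OracleBackend` returns stored ground-truth masks (from a phantom
  cohort) resampled to the working grid — the test and development backend.
* :class:`ExternalAdapter` shells out to a whole-body CT segmenter (e.g. a
  TotalSegmentator-style CLI) and aggregates its output labels through a
  configurable name map.

Backends run on a coarse isotropic working grid (default 3 mm, a fast mode
that saves time and memory); downstream intensity metrics resample masks
back to the native image grid so HU statistics use original voxel values.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .geometry import ImageVolume, VolumeGeometry

__all__ = [
    "LABELS",
    "LabelMask",
    "SegmentationResult",
    "BackendConfig",
    "SegmentationFailure",
    "OracleBackend",
    "ExternalAdapter",
    "make_backend",
    "segment",
    "resample_mask_to_grid",
    "label_present",
]

LABELS = ("aorta", "lungs_composite", "brachiocephalic_trunk")

#: default aggregation of an external segmenter's label names
DEFAULT_LABEL_MAP: dict[str, tuple[str, ...]] = {
    "aorta": ("aorta",),
    "lungs_composite": (
        "lung_upper_lobe_left",
        "lung_lower_lobe_left",
        "lung_upper_lobe_right",
        "lung_middle_lobe_right",
        "lung_lower_lobe_right",
    ),
    "brachiocephalic_trunk": ("brachiocephalic_trunk",),
}


class SegmentationFailure(RuntimeError):
    """Backend could not produce masks; the series is excluded like a corrupt file."""


@dataclass
class LabelMask:
    label: str
    geometry: VolumeGeometry
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if tuple(self.voxels.shape) != self.geometry.size:
            raise ValueError(
                f"mask shape {self.voxels.shape} != geometry size {self.geometry.size}"
            )

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class SegmentationResult:
    masks: dict[str, LabelMask]
    backend_id: str
    working_spacing: float


@dataclass
class BackendConfig:
    backend_id: str = "oracle"  # "oracle" | "external_adapter"
    working_spacing: float = 3.0
    label_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )
    # oracle: where ground-truth masks come from (in-memory mapping
    # {series_uid: {label: LabelMask}} or a directory written by the phantom
    # cohort generator)
    oracle_masks: Optional[Mapping[str, Mapping[str, LabelMask]]] = None
    oracle_dir: Optional[Path] = None
    # external adapter
    executable: str = "TotalSegmentator"

    def __post_init__(self) -> None:
        if self.working_spacing <= 0:
            raise ValueError("working_spacing must be > 0")


def label_present(mask: LabelMask, min_voxels: int = 10) -> bool:
    """True iff the mask has at least ``min_voxels`` true voxels.

    The small default threshold suppresses single-voxel segmentation speckle
    without hiding genuinely present anatomy.
    """
    return mask.count >= min_voxels


def working_grid(geometry: VolumeGeometry, spacing: float) -> VolumeGeometry:
    """Isotropic LPS-axis-aligned grid covering ``geometry``'s patient extent."""
    lo, hi = geometry.patient_bounds()
    extent = hi - lo
    size = tuple(int(np.floor(e / spacing)) + 1 for e in extent)
    return VolumeGeometry(
        origin=tuple(lo),
        spacing=(spacing, spacing, spacing),
        direction=np.eye(3),
        size=size,
    )


def resample_mask_to_grid(mask: LabelMask, target: VolumeGeometry) -> LabelMask:
    """Nearest-neighbor resampling of a boolean mask in patient coordinates.

    Each target voxel takes the value of the source voxel nearest to its
    patient-space center.  A center is considered inside the source as long
    as it falls within the source's physical voxel extent (half a voxel
    beyond the outermost center lattice), so grids whose boundaries are
    offset by sub-voxel amounts round-trip without eroding boundary-touching
    structures; centers beyond the extent are false.  Disjoint patient
    extents yield an all-false mask plus a warning.
    """
    centers = target.voxel_centers().reshape(-1, 3)
    cont = mask.geometry.patient_to_voxel(centers)
    size = np.asarray(mask.geometry.size)
    inside = np.all((cont >= -0.5) & (cont <= size - 0.5), axis=1)
    out = np.zeros(len(centers), dtype=bool)
    if inside.any():
        ii = np.clip(np.rint(cont[inside]).astype(np.int64), 0, size - 1)
        out[inside] = mask.voxels[ii[:, 0], ii[:, 1], ii[:, 2]]
    else:
        warnings.warn(
            f"resample target for label {mask.label!r} is disjoint from the "
            "source extent; returning an empty mask",
            stacklevel=2,
        )
    return LabelMask(mask.label, target, out.reshape(target.size))


class OracleBackend:
    """Returns stored ground-truth masks, resampled to the working grid.

    Masks are looked up by the volume's provenance (series identifier) either
    in an in-memory mapping or in a directory of NIfTI masks written by the
    phantom cohort generator.  Anatomy absent from the ground truth yields an
    all-false mask, never an error.
    """

    backend_id = "oracle"

    def __init__(self, config: BackendConfig):
        self.config = config

    def _lookup(self, series_uid: str) -> Mapping[str, LabelMask]:
        if self.config.oracle_masks is not None and series_uid in self.config.oracle_masks:
            return self.config.oracle_masks[series_uid]
        if self.config.oracle_dir is not None:
            from .phantom import load_ground_truth_masks  # cycle-free at call time

            masks = load_ground_truth_masks(Path(self.config.oracle_dir), series_uid)
            if masks is not None:
                return masks
        raise SegmentationFailure(f"no ground-truth masks for series {series_uid!r}")

    def segment(self, volume: ImageVolume) -> SegmentationResult:
        truth = self._lookup(volume.provenance)
        grid = working_grid(volume.geometry, self.config.working_spacing)
        masks = {}
        for label in LABELS:
            if label in truth:
                masks[label] = resample_mask_to_grid(truth[label], grid)
            else:
                masks[label] = LabelMask(label, grid, np.zeros(grid.size, dtype=bool))
        return SegmentationResult(masks, self.backend_id, self.config.working_spacing)


class ExternalAdapter:
    """Adapter for an external whole-body CT segmenter invoked as a subprocess.

    The adapter writes the volume to a temporary NIfTI, runs the configured
    executable, reads the per-structure NIfTI outputs, and aggregates them
    into the three pipeline labels through ``config.label_map``.  Any failure
    (missing executable, non-zero exit, unreadable output) raises
    :class:`SegmentationFailure`; the pipeline then drops the series with
    reason ``segmentation_failed``.
    """

    backend_id = "external_adapter"

    def __init__(self, config: BackendConfig):
        self.config = config

    def segment(self, volume: ImageVolume) -> SegmentationResult:
        import shutil
        import tempfile

        import nibabel as nib

        exe = shutil.which(self.config.executable)
        if exe is None:
            raise SegmentationFailure(
                f"external segmenter {self.config.executable!r} not on PATH"
            )
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            in_path = tmp / "volume.nii"
            affine = _lps_affine(volume.geometry)
            nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), in_path)
            out_dir = tmp / "seg"
            try:
                subprocess.run(
                    [exe, "-i", str(in_path), "-o", str(out_dir), "--fast"],
                    check=True,
                    capture_output=True,
                )
            except (OSError, subprocess.CalledProcessError) as exc:
                raise SegmentationFailure(f"segmenter failed: {exc}") from exc
            grid = working_grid(volume.geometry, self.config.working_spacing)
            masks = {}
            for label, sources in self.config.label_map.items():
                agg = np.zeros(grid.size, dtype=bool)
                for name in sources:
                    f = out_dir / f"{name}.nii.gz"
                    if not f.exists():
                        continue
                    img = nib.load(f)
                    src_geom = _geometry_from_nifti(img)
                    src = LabelMask(label, src_geom, np.asarray(img.dataobj) > 0)
                    agg |= resample_mask_to_grid(src, grid).voxels
                masks[label] = LabelMask(label, grid, agg)
            return SegmentationResult(
                masks, self.backend_id, self.config.working_spacing
            )


def _lps_affine(geometry: VolumeGeometry) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = geometry.index_to_patient_matrix
    affine[:3, 3] = geometry.origin
    affine[0, :] *= -1.0  # LPS -> RAS for the NIfTI container
    affine[1, :] *= -1.0
    return affine


def _geometry_from_nifti(img) -> VolumeGeometry:
    affine = img.affine.copy()
    affine[0, :] *= -1.0
    affine[1, :] *= -1.0
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return VolumeGeometry(
        origin=tuple(affine[:3, 3]),
        spacing=tuple(spacing),
        direction=lin / spacing,
        size=img.shape[:3],
    )


def make_backend(config: BackendConfig):
    if config.backend_id == "oracle":
        return OracleBackend(config)
    if config.backend_id == "external_adapter":
        return ExternalAdapter(config)
    raise ValueError(f"unknown backend {config.backend_id!r}")


def segment(volume: ImageVolume, config: BackendConfig) -> SegmentationResult:
    """Segment ``volume`` with the backend named in ``config``."""
    return make_backend(config).segment(volume)
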