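"""Voxel grids in patient space.

All geometry uses the DICOM LPS patient coordinate convention: +x toward the
patient's left, +y posterior, +z superior ("cranial" is the +z extreme).
A :class:`VolumeGeometry` maps voxel indices ``(i, j, k)`` to patient
coordinates via

    p(i, j, k) = origin + i*s0*d0 + j*s1*d1 + k*s2*d2

where ``d0, d1, d2`` are the columns of ``direction`` (in-plane axis 0,
in-plane axis 1, slice axis) and ``s`` the per-axis spacing in mm.  For an
axial acquisition the slice axis ``d2`` is aligned with patient z, so voxel
axis 2 indexes slices from caudal to cranial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGeometry", "ImageVolume", "GeometryError"]

# HU sanity bounds for rescaled CT intensities
HU_MIN = -1100.0
HU_MAX = 4000.0


class GeometryError(ValueError):
    """Raised for inconsistent grid geometry."""


@dataclass(frozen=True, eq=False)
class VolumeGeometry:
    """Origin/spacing/direction/size of a voxel grid in LPS patient space.

    Parameters
    ----------
    origin
        Patient-space position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing
        Per-axis voxel size (mm) for the two in-plane axes and the slice axis.
    direction
        3x3 matrix whose *columns* are the unit direction cosines of the three
        voxel axes in LPS coordinates.
    size
        Voxel counts per axis.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    direction: np.ndarray
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3):
            raise GeometryError(f"direction must be 3x3, got {d.shape}")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise GeometryError(f"size components must be >= 1, got {self.size}")
        norms = np.linalg.norm(d, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise GeometryError(f"direction columns must be unit norm, got {norms}")
        gram = d.T @ d
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise GeometryError("direction columns must be mutually orthogonal")

    def __eq__(self, other) -> bool:
        if not isinstance(other, VolumeGeometry):
            return NotImplemented
        return (
            self.origin == other.origin
            and self.spacing == other.spacing
            and self.size == other.size
            and np.array_equal(self.direction, other.direction)
        )

    def __hash__(self) -> int:
        return hash((self.origin, self.spacing, self.size))

    # -- coordinate transforms -------------------------------------------

    @property
    def index_to_patient_matrix(self) -> np.ndarray:
        """Columns scaled by spacing: maps index offsets to mm offsets."""
        return self.direction * np.asarray(self.spacing)

    def voxel_to_patient(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to LPS mm."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.index_to_patient_matrix.T + np.asarray(self.origin)

    def patient_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) LPS mm points to continuous voxel indices."""
        pts = np.asarray(points, dtype=float) - np.asarray(self.origin)
        inv = np.linalg.inv(self.index_to_patient_matrix)
        return pts @ inv.T

    def voxel_centers(self) -> np.ndarray:
        """Patient coordinates of every voxel center, shape ``size + (3,)``."""
        grids = np.meshgrid(
            *(np.arange(n, dtype=float) for n in self.size), indexing="ij"
        )
        idx = np.stack(grids, axis=-1)
        return self.voxel_to_patient(idx)

    def patient_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned LPS bounding box of the eight grid corners (mm)."""
        n = np.asarray(self.size, dtype=float) - 1.0
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])]
        )
        pts = self.voxel_to_patient(corners)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class ImageVolume:
    """Scalar CT volume in Hounsfield units with its grid geometry."""

    geometry: VolumeGeometry
    voxels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if tuple(self.voxels.shape) != self.geometry.size:
            raise GeometryError(
                f"voxel array shape {self.voxels.shape} != geometry size "
                f"{self.geometry.size}"
            )

    def validate_hu_range(self) -> None:
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise GeometryError(
                f"HU values out of sanity range [{HU_MIN}, {HU_MAX}]: "
                f"min={lo}, max={hi}"
            )
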