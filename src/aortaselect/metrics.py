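"""Per-series quantities the selection filters consume.

Three measurements drive the content-based filters:

* the thoracic slice range, taken from the lung mask (crop to the chest so a
  long scan's abdominal aorta does not dilute the statistic);
* the median aortic HU within that range — the contrast-phase detector
  (arterial-phase blood pool sits well above 150 HU, unenhanced blood near
  40–60 HU);
* edge-touch flags for the aorta mask on the cranial and lateral image
  boundaries, indicating a field of view that cuts off part of the aorta.

The caudal boundary is deliberately *not* checked: the descending aorta
always exits the chest inferiorly, so caudal touching is expected and must
not exclude a series.  Metrics are computed on the native image grid (masks
resampled back from the segmentation working grid) so HU statistics use
original voxel intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import ImageVolume, VolumeGeometry
from .imaging import SeriesRecord
from .segmentation import (
    LABELS,
    LabelMask,
    SegmentationResult,
    label_present,
    resample_mask_to_grid,
)

__all__ = [
    "SeriesMetrics",
    "MetricUndefined",
    "thoracic_bounds",
    "median_hu",
    "edge_touch_flags",
    "aorta_complete",
    "compute_series_metrics",
]


class MetricUndefined(ValueError):
    """A metric's precondition is not met (e.g. no aorta voxels in the thorax)."""


@dataclass
class SeriesMetrics:
    """Snapshot of everything the filter cascade needs for one series."""

    orientation_class: str = "unknown"
    volumetric: bool = False
    labels_present: dict[str, bool] = field(default_factory=dict)
    thoracic_slice_range: Optional[tuple[int, int]] = None
    median_aortic_hu: Optional[float] = None
    edge_cranial: Optional[bool] = None
    edge_lateral: Optional[bool] = None
    effective_slice_thickness: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "orientation_class": self.orientation_class,
            "volumetric": self.volumetric,
            "median_aortic_hu": self.median_aortic_hu,
            "edge_cranial": self.edge_cranial,
            "edge_lateral": self.edge_lateral,
            "effective_slice_thickness": self.effective_slice_thickness,
        }
        for label in LABELS:
            row[f"present_{label}"] = self.labels_present.get(label)
        if self.thoracic_slice_range is not None:
            row["thorax_lo"], row["thorax_hi"] = self.thoracic_slice_range
        return row


def thoracic_bounds(lungs: LabelMask, margin_slices: int = 0) -> tuple[int, int]:
    """Inclusive slice-index interval spanned by the lung mask, plus margin.

    The margin extends the interval by ``margin_slices`` on each side, clipped
    to the volume.  Raises :class:`MetricUndefined` on an empty lung mask (the
    label-presence filter runs first, so callers normally never hit this).
    """
    occupied = np.flatnonzero(lungs.voxels.any(axis=(0, 1)))
    if occupied.size == 0:
        raise MetricUndefined("empty lung mask: thoracic bounds undefined")
    n_slices = lungs.geometry.size[2]
    lo = max(int(occupied[0]) - margin_slices, 0)
    hi = min(int(occupied[-1]) + margin_slices, n_slices - 1)
    return lo, hi


def median_hu(
    volume: ImageVolume, aorta: LabelMask, bounds: tuple[int, int]
) -> float:
    """Median HU over aorta voxels whose slice index lies within ``bounds``.

    Uses the mid-pair-mean convention for even counts.  Raises
    :class:`MetricUndefined` when no aorta voxel falls inside the interval.
    """
    lo, hi = bounds
    sel = aorta.voxels.copy()
    sel[:, :, :lo] = False
    sel[:, :, hi + 1:] = False
    vals = volume.voxels[sel]
    if vals.size == 0:
        raise MetricUndefined("no aorta voxels within thoracic bounds")
    return float(np.median(vals))


def edge_touch_flags(
    aorta: LabelMask, geometry: VolumeGeometry, buffer_voxels: int = 0
) -> tuple[bool, bool]:
    """Does the aorta mask touch the cranial or lateral image boundary?

    ``edge_cranial`` is true when any aorta voxel lies in the boundary slice
    whose patient-z coordinate is maximal over the volume; ``edge_lateral``
    when any aorta voxel lies in either boundary plane of the in-plane axis
    most aligned with patient x (left–right).  Caudal and anterior/posterior
    boundaries are not checked.  ``buffer_voxels`` widens each checked
    boundary plane inward by that many voxels (default 0: the plane itself).

    Requires an axial volume (slice axis aligned with patient z) and a
    non-empty mask.
    """
    if not aorta.voxels.any():
        raise MetricUndefined("edge flags undefined for an empty aorta mask")
    d = geometry.direction
    if abs(d[2, 2]) < 0.5:
        raise ValueError("edge_touch_flags requires an axial volume")
    m = aorta.voxels
    b = buffer_voxels

    # cranial: the slice-axis end with the larger patient z
    if d[2, 2] > 0:
        cranial_block = m[:, :, m.shape[2] - 1 - b:]
    else:
        cranial_block = m[:, :, : 1 + b]
    edge_cranial = bool(cranial_block.any())

    # lateral: boundary planes of the in-plane axis most aligned with patient x
    lateral_axis = int(np.argmax(np.abs(d[0, :2])))
    planes = np.moveaxis(m, lateral_axis, 0)
    edge_lateral = bool(planes[: 1 + b].any() or planes[planes.shape[0] - 1 - b:].any())
    return edge_cranial, edge_lateral


def aorta_complete(flags: tuple[bool, bool]) -> bool:
    """True iff the aorta touches neither the cranial nor a lateral boundary."""
    return not flags[0] and not flags[1]


def compute_series_metrics(
    series: SeriesRecord,
    volume: ImageVolume,
    seg: SegmentationResult,
    *,
    margin_slices: int = 0,
    min_label_voxels: int = 10,
    edge_buffer_voxels: int = 0,
) -> SeriesMetrics:
    """Assemble the full metric snapshot for one series.

    Label presence is judged on the segmentation working grid; the lung and
    aorta masks are then resampled to the native grid for the slice-range,
    median-HU and edge computations.  Metrics whose prerequisites are missing
    stay ``None`` with an explanatory note; the filter cascade turns those
    into exclusions.
    """
    metrics = SeriesMetrics(
        orientation_class=series.orientation_class,
        volumetric=False,  # filled by the pipeline via is_volumetric
        effective_slice_thickness=(
            series.computed_slice_spacing
            if series.computed_slice_spacing is not None
            else series.reported_slice_thickness
        ),
    )
    metrics.labels_present = {
        label: label_present(seg.masks[label], min_label_voxels) for label in LABELS
    }
    if not metrics.labels_present.get("lungs_composite"):
        metrics.notes.append("lungs absent: thoracic bounds undefined")
        return metrics
    lungs_native = resample_mask_to_grid(seg.masks["lungs_composite"], volume.geometry)
    if not lungs_native.voxels.any():
        metrics.notes.append("lung mask empty after resampling to native grid")
        return metrics
    metrics.thoracic_slice_range = thoracic_bounds(lungs_native, margin_slices)

    if not metrics.labels_present.get("aorta"):
        metrics.notes.append("aorta absent: median HU and edge flags undefined")
        return metrics
    aorta_native = resample_mask_to_grid(seg.masks["aorta"], volume.geometry)
    if not aorta_native.voxels.any():
        metrics.notes.append("aorta mask empty after resampling to native grid")
        return metrics
    try:
        metrics.median_aortic_hu = median_hu(
            volume, aorta_native, metrics.thoracic_slice_range
        )
    except MetricUndefined:
        metrics.notes.append("no_aorta_in_thorax")
    if series.orientation_class == "axial":
        metrics.edge_cranial, metrics.edge_lateral = edge_touch_flags(
            aorta_native, volume.geometry, edge_buffer_voxels
        )
    return metrics
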