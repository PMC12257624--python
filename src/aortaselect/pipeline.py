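"""The series-selection cascade and its attrition accounting.

For every series the cascade evaluates, in fixed order:

1. ``axial3d``   — axial orientation and a volumetric (multi-slice) CT;
2. ``labels``    — lungs, aorta and brachiocephalic trunk all segmented
                   (chest is shown and the top of the arch is in view);
3. ``contrast``  — median aortic HU strictly greater than the threshold
                   (default 150 HU, the arterial-phase detector);
4. ``complete_aorta`` — aorta mask touches neither the cranial nor a lateral
                   image boundary;
5. ``thickness`` — effective slice thickness at most the maximum (default
                   3.0 mm inclusive, the thin-cut requirement).

The first failing step short-circuits the rest.  Within each study the series
with the highest median aortic HU among the survivors is selected (ties by
greater slice count, then lexicographically smallest series identifier), so
the output is one maximal-contrast series per study.  A study with no
surviving series is charged to the step at which its last surviving series
was eliminated; unreadable series and backend failures count as step-1
(corrupt-file) exclusions.  The whole pipeline is deterministic: repeated
runs over the same inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from .geometry import GeometryError
from .imaging import (
    CohortScan,
    CorruptSeriesError,
    SeriesRecord,
    StudyRecord,
    is_volumetric,
    load_volume,
)
from .metrics import SeriesMetrics, compute_series_metrics
from .segmentation import LABELS, BackendConfig, SegmentationFailure, make_backend

__all__ = [
    "STEPS",
    "PipelineConfig",
    "FilterDecision",
    "StepAttrition",
    "AttritionReport",
    "SelectedSeries",
    "SelectionManifest",
    "apply_series_filters",
    "select_best_series",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: exclusion steps in evaluation order (corrupt files are charged to step 1)
STEPS = ("axial3d", "labels", "contrast", "complete_aorta", "thickness")
_STEP_INDEX = {name: i for i, name in enumerate(STEPS)}


@dataclass
class PipelineConfig:
    """All thresholds of the cascade; the pipeline has no randomness."""

    hu_threshold: float = 150.0        # strict: exactly 150.0 is excluded
    max_slice_thickness: float = 3.0   # inclusive: exactly 3.0 mm passes
    axial_tolerance_deg: float = 10.0
    min_slices: int = 20
    min_label_voxels: int = 10
    margin_slices: int = 0
    edge_buffer_voxels: int = 0
    backend: BackendConfig = field(default_factory=BackendConfig)

    def __post_init__(self) -> None:
        if not (self.hu_threshold == self.hu_threshold):  # NaN guard
            raise ValueError("hu_threshold must be finite")
        if self.max_slice_thickness <= 0:
            raise ValueError("max_slice_thickness must be > 0")


@dataclass
class FilterDecision:
    series_uid: str
    step: str  # one of STEPS, or "corrupt"
    outcome: str  # "pass" | "excluded"
    reason: str = ""
    value: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "series_uid": self.series_uid,
                "step": self.step,
                "outcome": self.outcome,
                "reason": self.reason,
                "value": self.value,
            }
        )


@dataclass
class StepAttrition:
    step: str
    studies_excluded: int
    series_excluded: int
    studies_remaining: int


@dataclass
class AttritionReport:
    """Per-step study/series attrition with exact conservation."""

    initial_studies: int
    initial_series: int
    per_step: list[StepAttrition]
    selected_studies: int

    def validate(self) -> None:
        total_excluded = sum(s.studies_excluded for s in self.per_step)
        if self.initial_studies != self.selected_studies + total_excluded:
            raise ValueError(
                "attrition conservation violated: "
                f"{self.initial_studies} != {self.selected_studies} + {total_excluded}"
            )
        remaining = self.initial_studies
        for s in self.per_step:
            remaining -= s.studies_excluded
            if s.studies_remaining != remaining:
                raise ValueError(f"inconsistent remaining count at step {s.step}")

    def to_dict(self) -> dict:
        return {
            "initial_studies": self.initial_studies,
            "initial_series": self.initial_series,
            "per_step": [
                {
                    "step": s.step,
                    "studies_excluded": s.studies_excluded,
                    "series_excluded": s.series_excluded,
                    "studies_remaining": s.studies_remaining,
                }
                for s in self.per_step
            ],
            "selected_studies": self.selected_studies,
        }

    def write_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class SelectedSeries:
    study_uid: str
    series_uid: str
    median_aortic_hu: float
    slice_thickness: Optional[float]
    metrics: SeriesMetrics


@dataclass
class SelectionManifest:
    rows: list[SelectedSeries]
    decisions: list[FilterDecision]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "study_uid": row.study_uid,
                "series_uid": row.series_uid,
                "median_aortic_hu": row.median_aortic_hu,
                "slice_thickness": row.slice_thickness,
            }
            rec.update(row.metrics.to_row())
            records.append(rec)
        cols = ["study_uid", "series_uid", "median_aortic_hu", "slice_thickness"]
        return pd.DataFrame.from_records(records, columns=None if records else cols)

    def write_csv(self, path: Path | str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_decisions(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for d in self.decisions:
                fh.write(d.to_json() + "\n")


def apply_series_filters(
    series: SeriesRecord, metrics: SeriesMetrics, config: PipelineConfig
) -> list[FilterDecision]:
    """Evaluate the five-step cascade for one series, short-circuiting."""
    uid = series.series_uid
    decisions: list[FilterDecision] = []

    def fail(step: str, reason: str, value: Optional[float] = None):
        decisions.append(FilterDecision(uid, step, "excluded", reason, value))
        return decisions

    def ok(step: str, value: Optional[float] = None):
        decisions.append(FilterDecision(uid, step, "pass", "", value))

    # 1. axial, volumetric 3D CT
    if metrics.orientation_class != "axial":
        return fail("axial3d", f"orientation_{metrics.orientation_class}")
    if not metrics.volumetric:
        return fail("axial3d", "not_volumetric", float(series.slice_count))
    ok("axial3d")

    # 2. all three labels present
    missing = [lbl for lbl in LABELS if not metrics.labels_present.get(lbl)]
    if missing:
        return fail("labels", "missing_" + "+".join(missing))
    ok("labels")

    # 3. arterial-phase contrast: median aortic HU strictly above threshold
    if metrics.median_aortic_hu is None:
        return fail("contrast", "metric_unavailable:no_aorta_in_thorax")
    if not metrics.median_aortic_hu > config.hu_threshold:
        return fail("contrast", "median_hu_at_or_below_threshold",
                    metrics.median_aortic_hu)
    ok("contrast", metrics.median_aortic_hu)

    # 4. whole thoracic aorta in view
    if metrics.edge_cranial is None or metrics.edge_lateral is None:
        return fail("complete_aorta", "metric_unavailable:edge_flags")
    if metrics.edge_cranial or metrics.edge_lateral:
        where = "cranial" if metrics.edge_cranial else "lateral"
        return fail("complete_aorta", f"aorta_cutoff_{where}")
    ok("complete_aorta")

    # 5. thin-cut reconstruction
    if metrics.effective_slice_thickness is None:
        return fail("thickness", "metric_unavailable:slice_thickness")
    if metrics.effective_slice_thickness > config.max_slice_thickness:
        return fail("thickness", "slice_thickness_above_max",
                    metrics.effective_slice_thickness)
    ok("thickness", metrics.effective_slice_thickness)
    return decisions


def select_best_series(
    candidates: list[tuple[SeriesRecord, SeriesMetrics]]
) -> tuple[SeriesRecord, SeriesMetrics]:
    """Argmax of median aortic HU among filter survivors, deterministically.

    Ties break by greater slice count, then by lexicographically smallest
    series identifier.
    """
    if not candidates:
        raise ValueError("select_best_series requires at least one candidate")
    return min(
        candidates,
        key=lambda cm: (
            -cm[1].median_aortic_hu,
            -cm[0].slice_count,
            cm[0].series_uid,
        ),
    )


def run_pipeline(
    cohort: list[StudyRecord] | CohortScan,
    config: PipelineConfig,
    loader: Callable[[SeriesRecord], object] = load_volume,
) -> tuple[SelectionManifest, AttritionReport]:
    """Run the full cascade over a cohort and account for every study.

    Per-series failures (unreadable files, backend failures) are recorded and
    never abort the run.  Output ordering is fixed (studies and series sorted
    by identifier) so repeated runs are byte-identical.
    """
    if isinstance(cohort, CohortScan):
        studies = cohort.studies
    else:
        studies = cohort
    studies = sorted(studies, key=lambda s: s.study_uid)
    backend = make_backend(config.backend)

    decisions: list[FilterDecision] = []
    rows: list[SelectedSeries] = []
    study_fail_step: list[int] = []  # charged step index per excluded study
    series_excluded_per_step = [0] * len(STEPS)

    for study in studies:
        survivors: list[tuple[SeriesRecord, SeriesMetrics]] = []
        last_step_reached = -1
        for series in sorted(study.series, key=lambda s: s.series_uid):
            try:
                series_decisions, metrics = _evaluate_series(
                    series, config, backend, loader
                )
            except (CorruptSeriesError, GeometryError, SegmentationFailure) as exc:
                reason = (
                    "segmentation_failed"
                    if isinstance(exc, SegmentationFailure)
                    else "corrupt_series"
                )
                logger.warning("series %s dropped: %s", series.series_uid, exc)
                decisions.append(
                    FilterDecision(series.series_uid, "corrupt", "excluded", reason)
                )
                series_excluded_per_step[0] += 1
                last_step_reached = max(last_step_reached, 0)
                continue
            decisions.extend(series_decisions)
            last = series_decisions[-1]
            if last.outcome == "excluded":
                idx = _STEP_INDEX[last.step]
                series_excluded_per_step[idx] += 1
                last_step_reached = max(last_step_reached, idx)
            else:
                survivors.append((series, metrics))
        if survivors:
            best, best_metrics = select_best_series(survivors)
            rows.append(
                SelectedSeries(
                    study_uid=study.study_uid,
                    series_uid=best.series_uid,
                    median_aortic_hu=best_metrics.median_aortic_hu,
                    slice_thickness=best_metrics.effective_slice_thickness,
                    metrics=best_metrics,
                )
            )
        else:
            study_fail_step.append(max(last_step_reached, 0))

    per_step: list[StepAttrition] = []
    remaining = len(studies)
    for i, step in enumerate(STEPS):
        n_studies = sum(1 for s in study_fail_step if s == i)
        remaining -= n_studies
        per_step.append(
            StepAttrition(step, n_studies, series_excluded_per_step[i], remaining)
        )

    report = AttritionReport(
        initial_studies=len(studies),
        initial_series=sum(len(s.series) for s in studies),
        per_step=per_step,
        selected_studies=len(rows),
    )
    report.validate()
    return SelectionManifest(rows, decisions), report


def _evaluate_series(series, config, backend, loader):
    metrics: SeriesMetrics
    # cheap metadata checks first would reorder attrition, so the full metric
    # set is computed only when the series can actually reach those steps
    if series.orientation_class != "axial" or not is_volumetric(
        series, config.min_slices
    ):
        metrics = SeriesMetrics(
            orientation_class=series.orientation_class,
            volumetric=is_volumetric(series, config.min_slices),
        )
        return apply_series_filters(series, metrics, config), metrics
    volume = loader(series)
    seg = backend.segment(volume)
    metrics = compute_series_metrics(
        series,
        volume,
        seg,
        margin_slices=config.margin_slices,
        min_label_voxels=config.min_label_voxels,
        edge_buffer_voxels=config.edge_buffer_voxels,
    )
    metrics.volumetric = True
    return apply_series_filters(series, metrics, config), metrics
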