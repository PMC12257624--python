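"""Accuracy metrics and attrition tables for a selection run.

Two figures summarize how well the cascade curates a cohort:

* **exclusion accuracy** — of the studies a step excluded, the fraction a
  reviewer judged appropriately excluded (per step and pooled over steps);
* **inclusion accuracy** — of the series the pipeline selected, the fraction
  confirmed to depict the entire thoracic aorta.

In production the review labels come from physicians reading the excluded
studies and 3D renderings of the selected segmentations; on phantom cohorts
:func:`score_against_ground_truth` plays the reviewer using the generator's
stored expectations.  Undefined ratios (0 excluded, 0 selected) are reported
as absent, never as 0% or 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .pipeline import STEPS, AttritionReport, SelectionManifest, StepAttrition

__all__ = [
    "StepAccuracy",
    "AccuracySummary",
    "ConfusionSummary",
    "exclusion_accuracy",
    "inclusion_accuracy",
    "summarize_review",
    "attrition_table",
    "attrition_from_counts",
    "score_against_ground_truth",
]


def exclusion_accuracy(excluded: int, appropriate: int) -> Optional[float]:
    """Percent of excluded studies that were appropriately excluded.

    Returns ``None`` (absent) when nothing was excluded.
    """
    if excluded < 0 or appropriate < 0 or appropriate > excluded:
        raise ValueError(
            f"need 0 <= appropriate <= excluded, got {appropriate}/{excluded}"
        )
    if excluded == 0:
        return None
    return 100.0 * appropriate / excluded


def inclusion_accuracy(selected: int, confirmed: int) -> Optional[float]:
    """Percent of selected series confirmed to show the entire thoracic aorta."""
    if selected < 0 or confirmed < 0 or confirmed > selected:
        raise ValueError(
            f"need 0 <= confirmed <= selected, got {confirmed}/{selected}"
        )
    if selected == 0:
        return None
    return 100.0 * confirmed / selected


@dataclass
class StepAccuracy:
    step: str
    excluded: int
    appropriate: int
    accuracy_pct: Optional[float]


@dataclass
class AccuracySummary:
    per_step: list[StepAccuracy]
    pooled_excluded: int
    pooled_appropriate: int
    pooled_accuracy_pct: Optional[float]
    selected: int
    confirmed: int
    inclusion_accuracy_pct: Optional[float]

    def to_dict(self) -> dict:
        return {
            "per_step": [
                {
                    "step": s.step,
                    "excluded": s.excluded,
                    "appropriate": s.appropriate,
                    "accuracy_pct": s.accuracy_pct,
                }
                for s in self.per_step
            ],
            "pooled_excluded": self.pooled_excluded,
            "pooled_appropriate": self.pooled_appropriate,
            "pooled_accuracy_pct": self.pooled_accuracy_pct,
            "selected": self.selected,
            "confirmed": self.confirmed,
            "inclusion_accuracy_pct": self.inclusion_accuracy_pct,
        }


def summarize_review(
    per_step_counts: Iterable[tuple[str, int, int]],
    selected: int,
    confirmed: int,
) -> AccuracySummary:
    """Build the accuracy summary from reviewed counts.

    ``per_step_counts`` holds ``(step, studies_excluded, appropriately_excluded)``
    triples.  The pooled exclusion accuracy is the ratio of summed numerators
    to summed denominators, which equals the exclusion-weighted mean of the
    per-step accuracies.
    """
    steps = [
        StepAccuracy(step, exc, app, exclusion_accuracy(exc, app))
        for step, exc, app in per_step_counts
    ]
    pooled_exc = sum(s.excluded for s in steps)
    pooled_app = sum(s.appropriate for s in steps)
    return AccuracySummary(
        per_step=steps,
        pooled_excluded=pooled_exc,
        pooled_appropriate=pooled_app,
        pooled_accuracy_pct=exclusion_accuracy(pooled_exc, pooled_app),
        selected=selected,
        confirmed=confirmed,
        inclusion_accuracy_pct=inclusion_accuracy(selected, confirmed),
    )


def attrition_from_counts(
    initial_studies: int,
    exclusions: Iterable[tuple[str, int]],
    initial_series: int = 0,
) -> AttritionReport:
    """Build an :class:`AttritionReport` from per-step study exclusion counts.

    Useful for reproducing a published attrition flow from its printed
    numbers: the remaining-after-step sequence and the final selected count
    follow by successive subtraction.
    """
    per_step: list[StepAttrition] = []
    remaining = initial_studies
    for step, n in exclusions:
        remaining -= n
        per_step.append(StepAttrition(step, n, 0, remaining))
    report = AttritionReport(
        initial_studies=initial_studies,
        initial_series=initial_series,
        per_step=per_step,
        selected_studies=remaining,
    )
    report.validate()
    return report


def attrition_table(report: AttritionReport) -> pd.DataFrame:
    """Tabulate per-step exclusions, cohort share, and remaining studies.

    Cohort shares are rounded to two decimals; the final row carries the
    selected-study count and its share of the initial cohort.
    """
    report.validate()
    initial = report.initial_studies
    rows = []
    for s in report.per_step:
        rows.append(
            {
                "step": s.step,
                "studies_excluded": s.studies_excluded,
                "pct_of_initial": round(100.0 * s.studies_excluded / initial, 2)
                if initial
                else None,
                "studies_remaining": s.studies_remaining,
            }
        )
    rows.append(
        {
            "step": "selected",
            "studies_excluded": 0,
            "pct_of_initial": round(100.0 * report.selected_studies / initial, 2)
            if initial
            else None,
            "studies_remaining": report.selected_studies,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class ConfusionSummary:
    """Per-series agreement between a pipeline run and phantom ground truth."""

    n_series: int
    agreements: int
    false_exclusions_per_step: dict[str, int] = field(default_factory=dict)
    false_inclusions: int = 0
    step_mismatches: int = 0
    selection_mismatches: int = 0
    disagreements: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def n_disagreements(self) -> int:
        return len(self.disagreements)


def _observed_outcomes(manifest: SelectionManifest) -> dict[str, str]:
    """Terminal per-series outcome: exclusion step or 'selected_candidate'."""
    outcomes: dict[str, str] = {}
    for d in manifest.decisions:
        if d.outcome == "excluded":
            step = "axial3d" if d.step == "corrupt" else d.step
            outcomes[d.series_uid] = step
        else:
            outcomes.setdefault(d.series_uid, "selected_candidate")
            if d.step == STEPS[-1]:
                outcomes[d.series_uid] = "selected_candidate"
    return outcomes


def score_against_ground_truth(
    manifest: SelectionManifest,
    truth: Mapping[str, object],
) -> ConfusionSummary:
    """Compare a run's per-series outcomes with the generator's expectations.

    ``truth`` maps series identifiers to objects (or dicts) carrying an
    ``expected_outcome`` — an exclusion step name or ``selected_candidate``
    (the series passes every filter and competes in the final per-study
    argmax).  On unambiguous phantom cohorts every cell outside the diagonal
    should be zero.
    """
    observed = _observed_outcomes(manifest)
    selected_uids = {row.series_uid for row in manifest.rows}

    summary = ConfusionSummary(n_series=0, agreements=0)
    for uid, rec in truth.items():
        expected = (
            rec["expected_outcome"] if isinstance(rec, Mapping)
            else getattr(rec, "expected_outcome")
        )
        if uid not in observed:
            raise ValueError(f"series {uid!r} has ground truth but no decisions")
        got = observed[uid]
        summary.n_series += 1
        if got == expected:
            summary.agreements += 1
            continue
        summary.disagreements.append((uid, expected, got))
        if expected == "selected_candidate":
            summary.false_exclusions_per_step[got] = (
                summary.false_exclusions_per_step.get(got, 0) + 1
            )
        elif got == "selected_candidate":
            summary.false_inclusions += 1
            if uid in selected_uids:
                summary.selection_mismatches += 1
        else:
            summary.step_mismatches += 1
    return summary
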