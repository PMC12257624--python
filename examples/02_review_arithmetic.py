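"""Reproduce a cohort-curation report from its reviewed counts.

Given per-step counts of excluded studies and how many of them a reviewer
judged appropriately excluded, derive the per-step and pooled exclusion
accuracies, the inclusion accuracy of the selected series, and the full
attrition flow by successive subtraction from the initial cohort size.
The counts below are the worked example used throughout the test suite:
a 4184-study cohort filtered down to 3435 selected studies.
"""

from aortaselect import attrition_from_counts, attrition_table, summarize_review

REVIEW_COUNTS = [
    # (step, studies excluded, judged appropriately excluded)
    ("axial3d", 113, 110),
    ("labels", 392, 392),
    ("contrast", 221, 177),
    ("complete_aorta", 20, 19),
    ("thickness", 3, 3),
]
INITIAL_STUDIES = 4184
SELECTED, CONFIRMED = 3435, 3406


def main() -> None:
    summary = summarize_review(REVIEW_COUNTS, selected=SELECTED, confirmed=CONFIRMED)
    print("per-step exclusion accuracy:")
    for s in summary.per_step:
        print(f"  {s.step:15s} {s.appropriate:4d}/{s.excluded:<4d} = {s.accuracy_pct:6.2f}%")
    print(
        f"pooled: {summary.pooled_appropriate}/{summary.pooled_excluded} "
        f"= {summary.pooled_accuracy_pct:.1f}%"
    )
    print(
        f"inclusion accuracy: {CONFIRMED}/{SELECTED} "
        f"= {summary.inclusion_accuracy_pct:.2f}%"
    )

    report = attrition_from_counts(
        INITIAL_STUDIES, [(step, n) for step, n, _ in REVIEW_COUNTS]
    )
    print("\nattrition flow:")
    print(attrition_table(report).to_string(index=False))


if __name__ == "__main__":
    main()
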