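"""Printed reference tables from the eight-subject overnight study.

These per-subject cells (demographics and per-night stage epoch counts)
are the published summary of the validation cohort.  They serve two
purposes here: regression inputs for :func:`bcgsleep.evaluation.summary_stats`
(the printed means, SDs and pooled stage percentages must reproduce from
these cells) and calibration references for the synthetic generator's
default stage proportions.
"""

from __future__ import annotations

import numpy as np

from .evaluation import stage_rates, summary_stats

#: Subject demographics (eight healthy young adult men).
SUBJECT_INFO = {
    "age_years": [21, 22, 22, 23, 22, 21, 21, 22],
    "height_m": [1.79, 1.72, 1.70, 1.79, 1.70, 1.65, 1.69, 1.70],
    "weight_kg": [83, 54, 68, 67, 85, 55, 63, 60],
}

#: Scored stage epoch counts per subject, nights 2 and 3.
STAGE_EPOCHS = {
    "night2": {
        "WAKE": [33, 74, 95, 53, 31, 52, 32, 74],
        "REM": [123, 99, 85, 95, 101, 135, 108, 137],
        "LIGHT": [653, 515, 471, 488, 537, 597, 443, 575],
        "DEEP": [119, 206, 175, 184, 141, 140, 157, 170],
    },
    "night3": {
        "WAKE": [32, 60, 85, 65, 21, 57, 38, 33],
        "REM": [121, 102, 4, 63, 141, 156, 161, 123],
        "LIGHT": [597, 421, 581, 472, 517, 562, 528, 653],
        "DEEP": [150, 197, 98, 138, 129, 279, 171, 119],
    },
}


def subject_summary() -> dict[str, dict[str, float]]:
    """Mean and population SD of each demographic row."""
    out = {}
    for name, values in SUBJECT_INFO.items():
        mean, sd = summary_stats(values)
        out[name] = {"mean": mean, "sd": sd}
    return out


def stage_summary() -> dict[str, dict[str, dict[str, float]]]:
    """Per-night stage epoch mean, population SD and pooled %Rate."""
    out: dict = {}
    for night, stages in STAGE_EPOCHS.items():
        rates = stage_rates(stages)
        out[night] = {}
        for stage, counts in stages.items():
            mean, sd = summary_stats(counts)
            out[night][stage] = {"mean": mean, "sd": sd, "rate_pct": rates[stage]}
    return out


def render_stage_table() -> str:
    """The stage-count table with cells rounded to one decimal for display."""
    lines = []
    for night, stages in stage_summary().items():
        lines.append(night)
        for stage, cells in stages.items():
            lines.append(
                f"  {stage:<5} mean {cells['mean']:.1f}  SD {cells['sd']:.1f}"
                f"  %Rate {cells['rate_pct']:.1f}"
            )
    return "\n".join(lines)


def pooled_stage_fractions() -> dict[str, float]:
    """Overall stage fractions across both nights (generator calibration)."""
    totals = {
        s: float(
            np.sum(STAGE_EPOCHS["night2"][s]) + np.sum(STAGE_EPOCHS["night3"][s])
        )
        for s in STAGE_EPOCHS["night2"]
    }
    grand = sum(totals.values())
    return {s: v / grand for s, v in totals.items()}
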