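"""Experimental layout of the short-time nitrogen-response design.

The design has three pretreatment conditions (exponential growth on
ammonium, nitrogen starvation, and a nitrate spike) followed by four
parallel nitrogen treatments (no nitrogen, ammonium, nitrite, nitrate)
each sampled at 15 min, 45 min, and 18 h: 15 conditions in total,
usually with two biological replicates (30 samples).

Differential expression is always called against the ammonium
pretreatment, giving 12 treatment-by-time comparisons per gene.
"""

from __future__ import annotations

import pandas as pd

PRETREATMENTS = ("preNH4", "preN0", "preNO3")
TREATMENTS = ("noN", "NH4", "NO2", "NO3")
TIMEPOINTS = ("15min", "45min", "18h")

#: Ordered 15-condition layout used everywhere downstream.
CONDITIONS = PRETREATMENTS + tuple(
    f"{trt}_{tp}" for trt in TREATMENTS for tp in TIMEPOINTS
)

#: Ordered 12 comparisons (treatment x time vs the ammonium pretreatment).
COMPARISONS = tuple(c for c in CONDITIONS if c not in PRETREATMENTS)

#: Reference condition for differential-expression comparisons.
REFERENCE_CONDITION = "preNH4"

#: Conditions in which nitrogen is still available in the medium.  The
#: 300 uM doses are exhausted within a few hours, so the 18 h samples of
#: every treatment are effectively nitrogen-deplete.
N_AVAILABLE = {
    "preNH4": True,
    "preN0": False,
    "preNO3": True,
    **{f"noN_{tp}": False for tp in TIMEPOINTS},
    **{f"{trt}_{tp}": tp != "18h" for trt in ("NH4", "NO2", "NO3") for tp in TIMEPOINTS},
}


def split_condition(condition: str) -> tuple[str, str]:
    """Return ``(treatment, timepoint)`` for a condition label."""
    if condition in PRETREATMENTS:
        return condition, "pre"
    trt, tp = condition.split("_", 1)
    return trt, tp


def make_sample_metadata(n_replicates: int = 2) -> pd.DataFrame:
    """Build the sample sheet for the full design.

    Returns a data frame with one row per sample and columns
    ``sample_id, replicate, condition, treatment, timepoint,
    n_available``.  Sample ids look like ``NO3_15min_r1``.
    """
    rows = []
    for rep in range(1, n_replicates + 1):
        for cond in CONDITIONS:
            trt, tp = split_condition(cond)
            rows.append(
                {
                    "sample_id": f"{cond}_r{rep}",
                    "replicate": rep,
                    "condition": cond,
                    "treatment": trt,
                    "timepoint": tp,
                    "n_available": N_AVAILABLE[cond],
                }
            )
    return pd.DataFrame(rows)


def validate_metadata(meta: pd.DataFrame) -> None:
    """Check that a sample sheet covers the full design exactly once."""
    required = {"sample_id", "replicate", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    key = meta[["condition", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate (condition, replicate) pairs in metadata")
    present = set(meta["condition"])
    absent = [c for c in CONDITIONS if c not in present]
    if absent:
        raise ValueError(f"metadata missing conditions: {absent}")
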