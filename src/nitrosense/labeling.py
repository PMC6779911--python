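"""Metabolite composition and isotope-labeling rate summaries.

The labeling rate of a metabolite pool is reported as the percentage of
the pool that becomes labeled per hour, computed from a single
reference timepoint (default 3 h): rate = 100 * f(t_ref) / t_ref.  No
natural-abundance correction is applied to labeled fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def labeling_rate(series: pd.DataFrame, reference_time: float = 3.0) -> float:
    """Percent of the pool labeled per hour from the reference timepoint.

    ``series`` needs ``time_h`` and ``labeled_fraction`` columns.
    """
    t = series["time_h"].to_numpy(dtype=float)
    match = np.isclose(t, reference_time)
    if not match.any():
        raise ValueError(f"reference timepoint {reference_time} h not in series")
    f = float(series.loc[match, "labeled_fraction"].iloc[0])
    return 100.0 * f / reference_time


def labeling_rates(table: pd.DataFrame, reference_time: float = 3.0) -> pd.Series:
    """Per-metabolite labeling rates from a long labeling table."""
    return table.groupby("metabolite").apply(
        lambda g: labeling_rate(g, reference_time), include_groups=False
    ).rename("pct_per_hour")


def composition_percent(pools: pd.Series) -> pd.Series:
    """Each pool as a percentage of the total over the measured set."""
    x = pools.astype(float)
    if (x < 0).any():
        raise ValueError("pool sizes must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all pools are zero")
    return (100.0 * x / total).rename("percent")
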