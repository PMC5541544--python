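"""Exogenous driver series: fishing effort and an aggregate climate index.

Fishing effort is measured in tonne-days: days at sea of each vessel
targeting benthic fish multiplied by its tonnage, summed within years.  The
climate index aggregates z-scored environmental component series (signed so
that negative means colder) and is smoothed with a trailing moving average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["fishing_effort", "climate_index", "moving_average"]


def fishing_effort(records: pd.DataFrame, target_filter: str | None = "benthic") -> pd.Series:
    """Annual fishing effort in tonne-days.

    ``records`` needs columns year, vessel_id, tonnage_t, days_at_sea, target.
    Vessels whose target class differs from ``target_filter`` are excluded
    (pass None to keep all).  Effort is additive over disjoint vessel subsets.
    """
    df = records
    if (df["tonnage_t"] <= 0).any():
        raise ValueError("tonnage must be positive")
    if (df["days_at_sea"] < 0).any():
        raise ValueError("days at sea must be non-negative")
    if target_filter is not None:
        df = df[df["target"] == target_filter]
    eff = df["tonnage_t"] * df["days_at_sea"]
    return eff.groupby(df["year"]).sum().sort_index()


def climate_index(components: pd.DataFrame, baseline: tuple = (1981, 2010),
                  sign_map: dict | None = None) -> pd.DataFrame:
    """Aggregate climate index from annual component series.

    Each component (column, indexed by year) is z-scored with mean/sd over
    the baseline years and multiplied by its sign (+1/-1, so that negative
    always means colder); the index column is the sum across scaled
    components.  Linear in its components by construction.
    """
    lo, hi = baseline
    base = components.loc[(components.index >= lo) & (components.index <= hi)]
    if len(base) == 0:
        raise ValueError("baseline years not present in components")
    scaled = {}
    for c in components.columns:
        mu, sd = base[c].mean(), base[c].std(ddof=1)
        if sd == 0:
            raise ValueError(f"component {c} constant over baseline")
        sign = (sign_map or {}).get(c, 1)
        scaled[c] = sign * (components[c] - mu) / sd
    out = pd.DataFrame(scaled, index=components.index)
    out["index"] = out.sum(axis=1)
    return out


def moving_average(x: pd.Series, window: int = 5) -> pd.Series:
    """Trailing moving average (window ending in year t).

    Years with fewer than ``window`` prior observations come out missing.
    """
    if window > len(x):
        raise ValueError("window longer than series")
    return x.sort_index().rolling(window).mean()
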