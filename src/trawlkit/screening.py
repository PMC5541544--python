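"""Screening of gear-sensitive species.

The 1995 switch to a smaller-meshed survey trawl raised catchability of small
fish, inflating post-1995 biomass for some species and creating apparent
arrivals of species never caught before.  Before any community analysis,
species are removed when (a) their mean biomass in a post-change window
(default 1995-2000) is more than ``threshold`` (default 7) times their
pre-1995 mean, or (b) they were captured too infrequently before the change
to support a comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GEAR_CHANGE_YEAR, TrawlTable

__all__ = ["screen_gear_sensitive_species", "era_species_means"]


def era_species_means(table: TrawlTable, years: tuple) -> pd.Series:
    """Pooled zero-inflated geometric-mean biomass per species over a year span.

    All tows in the span count toward n for every species (absences are
    zeros); pooling is across all tows, not a mean of annual means.
    """
    lo, hi = years
    df = table.df[(table.df["year"] >= lo) & (table.df["year"] <= hi)]
    tows = table.trawls
    n = int(((tows["year"] >= lo) & (tows["year"] <= hi)).sum())
    out = {}
    for sp in table.species_list:
        b = df.loc[(df["species"] == sp) & (df["biomass_kg"] > 0), "biomass_kg"]
        m = len(b)
        out[sp] = 0.0 if (m == 0 or n == 0) else \
            (m / n) * float(np.exp(np.mean(np.log(b.to_numpy()))))
    return pd.Series(out)


def screen_gear_sensitive_species(table: TrawlTable, threshold: float = 7.0,
                                  post_window: tuple = (1995, 2000),
                                  min_pre_trawls: int = 1):
    """Remove species whose catches are confounded by the 1995 gear change.

    Excludes species whose pooled mean biomass in ``post_window`` is strictly
    more than ``threshold`` times the pre-1995 pooled mean, and species caught
    in fewer than ``min_pre_trawls`` tows before 1995.  Returns the filtered
    table and the list of excluded species.  Idempotent.
    """
    if len(table.df) == 0:
        raise ValueError("empty trawl table")
    pre_lo = table.year_range[0]
    if pre_lo >= GEAR_CHANGE_YEAR or table.year_range[1] < post_window[1]:
        raise ValueError("table must span pre-1995 years and the post window")

    pre = era_species_means(table, (pre_lo, GEAR_CHANGE_YEAR - 1))
    post = era_species_means(table, post_window)

    df_pre = table.df[table.df["year"] < GEAR_CHANGE_YEAR]
    pre_counts = df_pre[df_pre["biomass_kg"] > 0].groupby("species")["trawl_id"].nunique()

    excluded = []
    for sp in table.species_list:
        if pre_counts.get(sp, 0) < min_pre_trawls:
            excluded.append(sp)
        # strict inequality, with a relative guard so a ratio of exactly
        # `threshold` is retained despite exp/log round-off
        elif pre[sp] > 0 and post[sp] > threshold * pre[sp] * (1 + 1e-12):
            excluded.append(sp)
    return table.drop_species(excluded), excluded
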