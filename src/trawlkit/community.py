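"""Aggregation of trawl records into community matrices.

A community matrix cell (group, species) is the zero-inflated geometric-mean
biomass over *all* tows in the group — tows where the species was absent
enter as zeros, so the estimator's n counts every tow in the group and m only
the positive ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix, TrawlTable

__all__ = ["build_community_matrix", "normalize_rows", "annual_species_samples"]


def _period_of(year: int, period_breaks) -> tuple | None:
    for lo, hi in period_breaks:
        if lo <= year <= hi:
            return (lo, hi)
    return None


def _zinf_pivot(records: pd.DataFrame, group_key: pd.Series, n_trawls: pd.Series,
                species_list: list) -> pd.DataFrame:
    """Vectorized zero-inflated geometric mean per (group, species).

    ``group_key`` aligns with ``records`` rows; ``n_trawls`` counts all tows
    per group, so absences contribute zeros through the m/n factor without
    being materialized.
    """
    pos = records["biomass_kg"] > 0
    sub = pd.DataFrame({
        "_grp": group_key[pos].to_numpy(),
        "species": records.loc[pos, "species"].to_numpy(),
        "_logb": np.log(records.loc[pos, "biomass_kg"].to_numpy(dtype=float)),
    })
    agg = sub.groupby(["_grp", "species"], sort=False)["_logb"].agg(["count", "mean"])
    agg = agg.reset_index()
    n = agg["_grp"].map(n_trawls).to_numpy(dtype=float)
    agg["estimate"] = (agg["count"].to_numpy() / n) * np.exp(agg["mean"].to_numpy())
    mat = agg.pivot_table(index="_grp", columns="species", values="estimate",
                          fill_value=0.0, aggfunc="first")
    mat = mat.reindex(columns=species_list, fill_value=0.0)
    mat = mat.reindex(index=sorted(n_trawls.index), fill_value=0.0)
    mat.index.name = None
    mat.columns.name = None
    return mat


def build_community_matrix(table: TrawlTable, group_by: str = "year",
                           polygons=None, period_breaks=None) -> CommunityMatrix:
    """Aggregate a trawl table into a groups x species matrix of robust means.

    ``group_by`` is one of 'year', 'polygon-year' or 'polygon-period'.  For
    polygon groupings the table must already carry polygon assignments (see
    :func:`trawlkit.spatial.assign_trawls`) or ``polygons`` must be given, in
    which case assignment happens here (tows outside all polygons dropped with
    a warning).  'polygon-period' additionally needs ``period_breaks``.  Row
    labels are years, (polygon_id, year) or (polygon_id, (lo, hi)) tuples.
    """
    if group_by == "year":
        n_trawls = table.trawls.groupby("year").size()
        key = table.df["year"]
        mat = _zinf_pivot(table.df, key, n_trawls, table.species_list)
        mat.index = mat.index.astype(int)
        return CommunityMatrix(mat)

    if "polygon_id" not in table.trawls.columns:
        if polygons is None:
            raise ValueError("polygon grouping requires assigned polygons")
        from .spatial import assign_trawls
        table = assign_trawls(table, polygons)

    tows = table.trawls
    records = table.df
    if "polygon_id" not in records.columns:
        records = records.copy()
        records["polygon_id"] = records["trawl_id"].map(
            tows.set_index("trawl_id")["polygon_id"])

    if group_by == "polygon-year":
        tow_grp = pd.Series(list(zip(tows["polygon_id"], tows["year"])),
                            index=tows.index)
        rec_grp = pd.Series(list(zip(records["polygon_id"], records["year"])),
                            index=records.index)
    elif group_by == "polygon-period":
        if period_breaks is None:
            raise ValueError("polygon-period grouping requires period_breaks")
        tow_period = tows["year"].map(lambda y: _period_of(int(y), period_breaks))
        rec_period = records["year"].map(lambda y: _period_of(int(y), period_breaks))
        if tow_period.isna().any():
            warnings.warn(f"{int(tow_period.isna().sum())} tow(s) outside all "
                          "periods dropped", stacklevel=2)
        tows = tows[tow_period.notna()]
        records = records[rec_period.notna()]
        tow_grp = pd.Series(list(zip(tows["polygon_id"], tow_period[tow_period.notna()])),
                            index=tows.index)
        rec_grp = pd.Series(list(zip(records["polygon_id"],
                                     rec_period[rec_period.notna()])),
                            index=records.index)
    else:
        raise ValueError(f"unknown group_by: {group_by!r}")

    n_trawls = tow_grp.groupby(tow_grp).size()
    mat = _zinf_pivot(records, rec_grp, n_trawls, table.species_list)
    return CommunityMatrix(mat)


def normalize_rows(cm: CommunityMatrix) -> CommunityMatrix:
    """Divide each row by its sum; all-zero rows are left as zeros and flagged."""
    vals = cm.values
    sums = vals.sum(axis=1, keepdims=True)
    out = np.divide(vals, sums, out=np.zeros_like(vals), where=sums > 0)
    empty = [cm.row_labels[i] for i in np.flatnonzero(sums.ravel() == 0)]
    data = pd.DataFrame(out, index=cm.data.index, columns=cm.data.columns)
    return CommunityMatrix(data, normalized=True, empty_rows=empty)


def annual_species_samples(table: TrawlTable, species=None) -> dict:
    """Per-year vectors of biomass per tow (zeros included), for the jackknife.

    ``species`` may be a species code, a list of codes (their per-tow biomasses
    are summed: a community-subset total) or None for the whole-table total.
    """
    df = table.df
    if species is not None:
        if isinstance(species, str):
            species = [species]
        df = df[df["species"].isin(set(species))]
    tot = df.groupby("trawl_id")["biomass_kg"].sum()
    tows = table.trawls
    vals = tows["trawl_id"].map(tot).fillna(0.0).to_numpy(dtype=float)
    years = tows["year"].to_numpy(dtype=int)
    return {int(y): vals[years == y] for y in np.unique(years)}
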