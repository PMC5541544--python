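"""Readers and writers for the package's delimited-text interfaces.

All files are comma-separated UTF-8 with a header row and '.' decimals.
Trawl CSV columns: trawl_id, year, lat, lon, depth_m, species, biomass_kg.
Trait CSV columns: species, vertical_position, body_length_cm, doubling_time,
trophic_level, aggregation, food_niche.  Polygons travel as GeoJSON
FeatureCollections with properties {polygon_id, mean_depth_m}.
"""

from __future__ import annotations

import json

import pandas as pd

from .datatypes import TRAWL_COLUMNS, TrawlTable, validate_traits
from .spatial import PolygonSet, polygons_from_geojson, polygons_to_geojson

__all__ = [
    "read_trawl_table",
    "write_trawl_table",
    "read_traits",
    "write_traits",
    "read_polygons",
    "write_polygons",
    "read_effort",
    "read_climate_components",
]

_NUMERIC = {"year": int, "lat": float, "lon": float, "depth_m": float,
            "biomass_kg": float}


def read_trawl_table(path) -> TrawlTable:
    """Read and validate a trawl CSV.

    Raises a schema error naming any missing column; unparseable numerics and
    invalid rows (negative biomass, non-positive depth) raise with the
    offending line number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRAWL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trawl file {path} missing column(s): {missing}")
    for col, typ in _NUMERIC.items():
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"unparseable {col} at line {line} of {path}") from None
        if typ is int:
            df[col] = df[col].astype(int)
    for col, pred, msg in [("biomass_kg", lambda s: s < 0, "negative biomass"),
                           ("depth_m", lambda s: s <= 0, "non-positive depth")]:
        bad = pred(df[col])
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{msg} at line {line} of {path}")
    return TrawlTable(df[TRAWL_COLUMNS])


def write_trawl_table(table: TrawlTable, path) -> None:
    """Write a trawl table; a write/read round trip reproduces records exactly."""
    out = table.df[TRAWL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.17g")


def read_traits(path) -> pd.DataFrame:
    """Read and validate a species trait CSV (indexed by species)."""
    return validate_traits(pd.read_csv(path))


def write_traits(traits: pd.DataFrame, path) -> None:
    df = traits.reset_index() if traits.index.name == "species" else traits
    df.to_csv(path, index=False, float_format="%.17g")


def read_polygons(path) -> PolygonSet:
    with open(path) as fh:
        return polygons_from_geojson(json.load(fh))


def write_polygons(polys: PolygonSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(polygons_to_geojson(polys), fh)


def read_effort(path) -> pd.DataFrame:
    """Read a fishing-effort CSV (year, vessel_id, tonnage_t, days_at_sea, target)."""
    df = pd.read_csv(path)
    req = ["year", "vessel_id", "tonnage_t", "days_at_sea", "target"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"effort file missing column(s): {missing}")
    return df


def read_climate_components(path) -> pd.DataFrame:
    """Read annual climate component series (year column + one per component)."""
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError("climate file missing 'year' column")
    return df.set_index("year")
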