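"""Core data containers for trawl-survey community analysis.

The atomic observation is a species biomass caught in one trawl tow, with
space/time/gear metadata. Everything downstream (annual biomass series,
community matrices, indicator series) is built from tables of such records.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TRAWL_COLUMNS",
    "TRAIT_COLUMNS",
    "NUMERIC_TRAITS",
    "CATEGORICAL_TRAITS",
    "GEAR_CHANGE_YEAR",
    "TrawlTable",
    "CommunityMatrix",
    "IndicatorSeries",
    "AnalysisConfig",
    "validate_traits",
]

#: Required columns of a trawl table, in canonical order.
TRAWL_COLUMNS = ["trawl_id", "year", "lat", "lon", "depth_m", "species", "biomass_kg"]

#: Trait table columns: species code plus six functional traits.
NUMERIC_TRAITS = ["body_length_cm", "doubling_time", "trophic_level"]
CATEGORICAL_TRAITS = ["vertical_position", "aggregation", "food_niche"]
TRAIT_COLUMNS = ["species"] + CATEGORICAL_TRAITS[:1] + NUMERIC_TRAITS + CATEGORICAL_TRAITS[1:]

#: First survey year fished with the new (small-mesh) gear.
GEAR_CHANGE_YEAR = 1995


def _gear_era(years: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(years) < GEAR_CHANGE_YEAR, "pre1995", "post1995")


@dataclass
class TrawlTable:
    """A validated table of species-per-trawl biomass observations.

    ``df`` holds one row per (trawl, species) with positive or zero biomass;
    absences are implicit (no row) and are made explicit as zeros when a
    community matrix is built.  ``gear_era`` is derived from ``year``:
    ``pre1995`` iff year <= 1994.
    """

    df: pd.DataFrame
    species_list: list = field(default_factory=list)
    year_range: tuple = (0, 0)
    #: one row per tow (trawl_id, year, lat, lon, depth_m[, polygon_id]);
    #: preserved through species subsetting so tow counts never shrink when
    #: a tow's only catches are filtered species
    trawls: pd.DataFrame | None = None

    def __post_init__(self):
        df = self.df
        missing = [c for c in TRAWL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trawl table missing required column(s): {missing}")
        if len(df) and (df["biomass_kg"] < 0).any():
            bad = df.index[df["biomass_kg"] < 0][0]
            raise ValueError(f"negative biomass at row {bad}")
        if len(df) and (df["depth_m"] <= 0).any():
            bad = df.index[df["depth_m"] <= 0][0]
            raise ValueError(f"non-positive depth at row {bad}")
        df = df.copy()
        df["gear_era"] = _gear_era(df["year"].to_numpy())
        self.df = df
        if not self.species_list:
            self.species_list = sorted(df["species"].unique().tolist())
        if self.year_range == (0, 0):
            if len(df):
                self.year_range = (int(df["year"].min()), int(df["year"].max()))
            else:
                self.year_range = (0, -1)
        unknown = set(df["species"]) - set(self.species_list)
        if unknown:
            raise ValueError(f"records reference species outside species_list: {sorted(unknown)}")
        if self.trawls is None:
            cols = ["trawl_id", "year", "lat", "lon", "depth_m"]
            self.trawls = df[cols].drop_duplicates("trawl_id").reset_index(drop=True)
        if len(df):
            lo, hi = self.year_range
            yrs = df["year"]
            if (yrs < lo).any() or (yrs > hi).any():
                raise ValueError("record year outside year_range")

    @property
    def years(self) -> np.ndarray:
        lo, hi = self.year_range
        return np.arange(lo, hi + 1)

    @property
    def n_trawls(self) -> int:
        return len(self.trawls)

    def subset_species(self, keep) -> "TrawlTable":
        keep = [s for s in self.species_list if s in set(keep)]
        sub = self.df[self.df["species"].isin(keep)].reset_index(drop=True)
        return TrawlTable(sub, species_list=keep, year_range=self.year_range,
                          trawls=self.trawls)

    def drop_species(self, drop) -> "TrawlTable":
        return self.subset_species([s for s in self.species_list if s not in set(drop)])

    def trawl_index(self) -> pd.DataFrame:
        """One row per tow (id, year, lat, lon, depth), deduplicated."""
        return self.trawls


@dataclass
class CommunityMatrix:
    """Sites-or-years x species abundance matrix.

    ``data`` is a DataFrame whose index labels groups (years, polygon-years or
    polygon-periods) and whose columns are species codes.  When ``normalized``
    each non-empty row sums to one; all-zero rows are recorded in
    ``empty_rows`` and left untouched.
    """

    data: pd.DataFrame
    normalized: bool = False
    empty_rows: list = field(default_factory=list)

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        if len(vals) and (vals < 0).any():
            raise ValueError("community matrix contains negative abundances")
        if self.normalized and len(vals):
            sums = vals.sum(axis=1)
            nonzero = sums > 0
            if nonzero.any() and not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise ValueError("normalized matrix has non-unit row sums")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def row_labels(self):
        return list(self.data.index)

    @property
    def species(self):
        return list(self.data.columns)


@dataclass
class IndicatorSeries:
    """A named annual time series with optional jackknife standard errors."""

    name: str
    years: np.ndarray
    values: np.ndarray
    ses: np.ndarray | None = None
    subset: str = "all"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.ses is not None:
            self.ses = np.asarray(self.ses, dtype=float)
            if len(self.ses) != len(self.values):
                raise ValueError("ses length mismatch")

    def at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"year {year} not in series {self.name!r}")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        d = {"year": self.years, "value": self.values}
        if self.ses is not None:
            d["se"] = self.ses
        return pd.DataFrame(d)


@dataclass
class AnalysisConfig:
    """Knobs of the indicator pipeline, with the defaults used throughout.

    ``period_breaks`` are the multi-year groupings used for the polygon-period
    clustering; they are chosen so that no period straddles the start of the
    collapse (1990) or the gear change (1995).
    """

    window_length: int = 5
    n_randomizations: int = 999
    n_clusters: int = 7
    nmds_dimensions: int = 2
    gear_ratio_threshold: float = 7.0
    min_years_present: int = 30
    reference_year: int = 1981
    period_breaks: tuple = (
        (1981, 1984),
        (1985, 1989),
        (1990, 1994),
        (1995, 2001),
        (2002, 2006),
        (2007, 2013),
    )
    rng_seed: int = 0
    focal_species: tuple = ()
    nmds_starts: int = 20

    def __post_init__(self):
        for name in ("window_length", "n_randomizations", "n_clusters", "nmds_dimensions",
                     "min_years_present"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        pb = [tuple(p) for p in self.period_breaks]
        for (a0, a1), (b0, b1) in zip(pb, pb[1:]):
            if a1 >= b0:
                raise ValueError("period breaks must be disjoint and ordered")
        self.period_breaks = tuple(pb)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "period_breaks" in raw:
            raw["period_breaks"] = tuple(tuple(p) for p in raw["period_breaks"])
        if "focal_species" in raw:
            raw["focal_species"] = tuple(raw["focal_species"])
        return cls(**raw)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a species trait table and return it indexed by species.

    Requires the six functional traits, no missing values, and strictly
    positive numeric traits (trophic level must additionally be >= 1).
    """
    df = traits.copy()
    if "species" in df.columns:
        df = df.set_index("species")
    required = NUMERIC_TRAITS + CATEGORICAL_TRAITS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing column(s): {missing}")
    df = df[required]
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing trait values for species: {bad}")
    for c in NUMERIC_TRAITS:
        df[c] = pd.to_numeric(df[c])
        if (df[c] <= 0).any():
            raise ValueError(f"numeric trait {c} must be strictly positive")
    if (df["trophic_level"] < 1).any():
        warnings.warn("trophic_level below 1 is unusual", stacklevel=2)
    return df
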