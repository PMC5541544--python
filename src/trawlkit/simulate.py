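"""Synthetic depth-stratified trawl surveys with regime dynamics.

The generator emulates the statistical structure the indicator pipeline
assumes, with the generating parameters exposed as ground truth:

* species-year expected log biomass follows
  ``log B_(s,t) = baseline_s + gamma_s * D_t + affinity_s * S_t + delta_(s,t)``
  where ``D_t`` is a common driver defined piecewise by regime phases
  (stable, synchronous decline, shifted regime, compositional recovery,
  slow biomass growth), ``S_t`` a regime-shift signal that transfers
  dominance between species, and ``delta`` species-year noise;
* per tow, local density is modulated by a Gaussian depth niche
  ``exp(-(depth_p - mu_s)^2 / (2 w_s^2))``; presence is Bernoulli with
  probability ``logistic(slope_s * log density)`` and positive catches are
  lognormal around the density;
* from 1995 onward densities are multiplied by a size-dependent gear factor
  ``exp(k (Lbar - L_s) / Lbar)`` clamped to [1, 10] — smaller fish are caught
  more by the new gear;
* polygon depths follow a smooth latitudinal gradient plus noise, so depth
  and geography are partially confounded as on a real shelf.

All randomness flows through a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely import contains_xy
from shapely.geometry import box

from .datatypes import GEAR_CHANGE_YEAR, TrawlTable
from .spatial import PolygonSet, build_voronoi_polygons

__all__ = ["ScenarioConfig", "GroundTruth", "simulate_survey",
           "default_collapse_scenario", "default_species_params"]

PHASE_KINDS = ("stable", "synchronous_decline", "shifted_regime",
               "compositional_recovery", "biomass_growth")


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic survey scenario.

    ``phases`` is a tuple of (start_year, end_year, kind, driver_slope);
    the intervals must tile ``years``.  ``species`` holds one row per species
    with the generating parameters (see :func:`default_species_params`);
    when None it is built from the seed at simulation time.
    """

    n_species: int = 30
    n_polygons: int = 150
    years: tuple = (1981, 2013)
    trawls_per_year: tuple = (421.0, 62.0)
    min_trawls: int = 50
    phases: tuple = (
        (1981, 1986, "stable", 0.0),
        (1987, 1994, "synchronous_decline", -0.35),
        (1995, 2004, "shifted_regime", 0.0),
        (2005, 2009, "compositional_recovery", 0.10),
        (2010, 2013, "biomass_growth", 0.12),
    )
    species: pd.DataFrame | None = None
    gear_k: float = 1.2
    gear_clamp: tuple = (1.0, 10.0)
    sigma_species_year: float = 0.15
    sigma_trawl: float = 0.8
    trawl_depth_sd: float = 8.0
    bbox: tuple = (-55.0, 46.0, -48.0, 55.0)  # lon_min, lat_min, lon_max, lat_max
    depth_base: float = 80.0
    depth_gain: float = 400.0
    depth_noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.years
        cur = lo
        for (a, b, kind, _slope) in self.phases:
            if a != cur or b < a:
                raise ValueError("phase intervals must tile the year range")
            if kind not in PHASE_KINDS:
                raise ValueError(f"unknown phase kind {kind!r}")
            cur = b + 1
        if cur != hi + 1:
            raise ValueError("phase intervals must tile the year range")
        for name in ("sigma_species_year", "sigma_trawl", "trawl_depth_sd",
                     "depth_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gear_clamp[0] <= 0:
            raise ValueError("gear multipliers must be positive")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def phase_of(self, year: int) -> str:
        for (a, b, kind, _s) in self.phases:
            if a <= year <= b:
                return kind
        raise KeyError(year)

    def phase_years(self, kind: str) -> list:
        return [y for y in self.year_list if self.phase_of(int(y)) == kind]

    def driver(self) -> pd.Series:
        """Common driver D_t: cumulative sum of phase slopes, 0 in year 1."""
        years = self.year_list
        slopes = {y: s for (a, b, _k, s) in self.phases for y in range(a, b + 1)}
        d = np.zeros(len(years))
        for i in range(1, len(years)):
            d[i] = d[i - 1] + slopes[int(years[i])]
        return pd.Series(d, index=years)

    def shift_signal(self) -> pd.Series:
        """Regime-shift signal S_t: 0 before the shifted regime, ramping to 1
        across it, decaying to 0.4 through compositional recovery and to 0.3
        over the growth phase (the shift only partially reverses)."""
        years = self.year_list
        s = np.zeros(len(years))
        level = 0.0
        for (a, b, kind, _sl) in self.phases:
            span = b - a + 1
            idx = np.flatnonzero((years >= a) & (years <= b))
            if kind == "shifted_regime":
                s[idx] = level + (1.0 - level) * (np.arange(1, span + 1) / span)
            elif kind == "compositional_recovery":
                s[idx] = level + (0.4 - level) * (np.arange(1, span + 1) / span)
            elif kind == "biomass_growth" and level > 0.3:
                s[idx] = level + (0.3 - level) * (np.arange(1, span + 1) / span)
            else:
                s[idx] = level
            level = s[idx[-1]] if len(idx) else level
        return pd.Series(s, index=years)

    def gear_multipliers(self) -> np.ndarray:
        L = self.species["body_length_cm"].to_numpy(dtype=float)
        Lbar = L.mean()
        g = np.exp(self.gear_k * (Lbar - L) / Lbar)
        return np.clip(g, *self.gear_clamp)


@dataclass
class GroundTruth:
    """Noiseless expectations behind a simulated survey."""

    log_biomass: pd.DataFrame  # years x species: regional log B_(s,t)
    expected_log_catch: pd.DataFrame  # + mean log depth kernel + gear factor
    presence_rate: pd.DataFrame  # exact Bernoulli mean at the realized tows
    true_window_synchrony: pd.DataFrame  # phi on noiseless expected biomasses
    depth_structuring: float  # mean over species of var_p(log kernel)
    phases: tuple = ()

    def phase_years(self, kind: str) -> list:
        return [y for (a, b, k, _s) in self.phases if k == kind
                for y in range(a, b + 1)]


def default_species_params(n_species: int, rng: np.random.Generator) -> pd.DataFrame:
    """Per-species generating parameters for the default collapse scenario.

    Four dominant 'commercial' species (large-bodied, high driver loading)
    plus ``n_species - 4`` others.  Species 'SP02' gains dominance during the
    shifted regime (emulating a transfer from the collapsed top predator to a
    mid-trophic winner) and its traits are made central in trait space so the
    dominance shift depresses functional dispersion.
    """
    n = n_species
    codes = [f"SP{i + 1:02d}" for i in range(n)]
    baseline = np.empty(n)
    baseline[:4] = np.log([140.0, 60.0, 35.0, 25.0])[: min(4, n)]
    baseline[4:] = rng.normal(np.log(3.0), 0.8, size=max(0, n - 4))
    gamma = np.empty(n)
    gamma[:4] = [1.25, 1.0, 1.1, 0.95][: min(4, n)]
    gamma[4:] = rng.uniform(0.4, 0.9, size=max(0, n - 4))
    body = np.empty(n)
    body[:4] = [150.0, 120.0, 90.0, 70.0][: min(4, n)]
    body[4:] = np.exp(rng.normal(np.log(35.0), 0.45, size=max(0, n - 4)))
    mu = rng.uniform(80.0, 520.0, size=n)
    w = rng.uniform(70.0, 160.0, size=n)
    affinity = np.zeros(n)
    if n >= 2:
        affinity[1] = 1.6  # the shift winner
        affinity[0] = -0.6  # the collapsed dominant stays suppressed
    if n > 6:
        idx = rng.choice(np.arange(4, n), size=min(4, n - 4), replace=False)
        affinity[idx] = rng.uniform(-0.5, 0.8, size=len(idx))

    doubling = np.exp(rng.normal(np.log(4.0), 0.5, size=n))
    trophic = np.round(rng.uniform(2.8, 4.6, size=n), 2)
    vert_levels = ["demersal", "benthopelagic", "bathydemersal"]
    agg_levels = ["solitary", "shoaling", "schooling", "aggregating"]
    niche_levels = ["piscivore", "benthivore", "planktivore", "generalist", "crustivore"]
    vertical = rng.choice(vert_levels, size=n)
    aggregation = rng.choice(agg_levels, size=n)
    food = rng.choice(niche_levels, size=n)

    df = pd.DataFrame({
        "species": codes,
        "baseline_log_biomass": baseline,
        "driver_loading": gamma,
        "shift_affinity": affinity,
        "depth_mu": mu,
        "depth_w": w,
        "detection_slope": np.full(n, 1.0),
        "body_length_cm": body,
        "doubling_time": doubling,
        "trophic_level": trophic,
        "vertical_position": vertical,
        "aggregation": aggregation,
        "food_niche": food,
        "commercial": [i < 4 for i in range(n)],
    }).set_index("species")
    if n >= 2:
        # make the shift winner trait-central: numeric traits at pool medians,
        # categorical traits at the modal levels
        win = codes[1]
        for c in ("body_length_cm", "doubling_time", "trophic_level"):
            df.loc[win, c] = float(df[c].median())
        for c in ("vertical_position", "aggregation", "food_niche"):
            df.loc[win, c] = df[c].mode().iloc[0]
    return df


def default_collapse_scenario(seed: int = 0) -> ScenarioConfig:
    """The ready-made four-phase collapse/shift/recovery scenario."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9021]))
    cfg = ScenarioConfig(seed=seed)
    cfg.species = default_species_params(cfg.n_species, rng)
    return cfg


def _sample_in_polygon(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = geom.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        need = max(8, int(1.8 * (n - got)))
        xs = rng.uniform(minx, maxx, need)
        ys = rng.uniform(miny, maxy, need)
        ok = contains_xy(geom, xs, ys)
        take = min(n - got, int(ok.sum()))
        out[got: got + take] = np.column_stack([xs[ok], ys[ok]])[:take]
        got += take
    return out


def simulate_survey(cfg: ScenarioConfig):
    """Generate one survey realization.

    Returns (TrawlTable, traits DataFrame, PolygonSet, GroundTruth); fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.species is None:
        cfg.species = default_species_params(cfg.n_species, rng)
    sp = cfg.species
    n_sp = len(sp)
    codes = sp.index.tolist()
    years = cfg.year_list
    n_years = len(years)

    # --- spatial frame: Voronoi polygons on a latitudinal depth gradient
    lon0, lat0, lon1, lat1 = cfg.bbox
    seeds = np.column_stack([rng.uniform(lon0, lon1, cfg.n_polygons),
                             rng.uniform(lat0, lat1, cfg.n_polygons)])
    boundary = box(lon0, lat0, lon1, lat1)
    polys = build_voronoi_polygons(seeds, boundary)
    lat_frac = (seeds[:, 1] - lat0) / (lat1 - lat0)
    depth_p = cfg.depth_base + cfg.depth_gain * lat_frac \
        + rng.normal(0, cfg.depth_noise_sd, cfg.n_polygons)
    depth_p = np.clip(depth_p, 20.0, None)
    t = polys.table.copy()
    t["mean_depth_m"] = depth_p
    polys = PolygonSet(t)

    # --- regional dynamics
    D = cfg.driver()
    S = cfg.shift_signal()
    base = sp["baseline_log_biomass"].to_numpy()
    gamma = sp["driver_loading"].to_numpy()
    affinity = sp["shift_affinity"].to_numpy()
    delta = rng.normal(0, cfg.sigma_species_year, size=(n_years, n_sp))
    logB_true = base[None, :] + np.outer(D.to_numpy(), gamma) \
        + np.outer(S.to_numpy(), affinity)
    logB = logB_true + delta

    # --- depth niches and gear factors
    mu = sp["depth_mu"].to_numpy()
    w = sp["depth_w"].to_numpy()
    log_kernel_p = -((depth_p[:, None] - mu[None, :]) ** 2) / (2 * w[None, :] ** 2)
    gear = cfg.gear_multipliers()
    slope = sp["detection_slope"].to_numpy()

    # --- tows
    mean_t, sd_t = cfg.trawls_per_year
    counts = np.maximum(cfg.min_trawls,
                        np.round(rng.normal(mean_t, sd_t, n_years))).astype(int)
    rows = []
    presence_rate = np.zeros((n_years, n_sp))
    tow_records = []
    tid = 0
    for yi, year in enumerate(years):
        n_t = counts[yi]
        # stratified allocation: tows spread near-evenly across polygons
        # (strata), remainder assigned at random — emulates a random
        # depth-stratified design and keeps the sampled depth distribution
        # stable between years
        per = n_t // cfg.n_polygons
        pidx = np.repeat(np.arange(cfg.n_polygons), per)
        # remainder follows a fixed round-robin over strata, as a standing
        # survey design would; only tow positions within cells are random
        extra = np.arange(n_t - per * cfg.n_polygons) % cfg.n_polygons
        pidx = np.concatenate([pidx, extra])
        # sample tow locations polygon by polygon
        locs = np.empty((n_t, 2))
        for p in np.unique(pidx):
            sel = np.flatnonzero(pidx == p)
            locs[sel] = _sample_in_polygon(polys.table.loc[p, "geometry"],
                                           len(sel), rng)
        depths = np.clip(depth_p[pidx] + rng.normal(0, cfg.trawl_depth_sd, n_t),
                         5.0, None)
        log_kernel_t = -((depths[:, None] - mu[None, :]) ** 2) / (2 * w[None, :] ** 2)
        log_d = logB[yi][None, :] + log_kernel_t
        if year >= GEAR_CHANGE_YEAR:
            log_d = log_d + np.log(gear)[None, :]
        p_pos = expit(slope[None, :] * log_d)
        presence_rate[yi] = p_pos.mean(axis=0)
        present = rng.random((n_t, n_sp)) < p_pos
        catch = np.exp(log_d + rng.normal(0, cfg.sigma_trawl, (n_t, n_sp)))
        ti, si = np.nonzero(present)
        ids = np.array([f"T{year}_{i:04d}" for i in range(n_t)])
        tow_records.append(pd.DataFrame({
            "trawl_id": ids, "year": year, "lat": locs[:, 1], "lon": locs[:, 0],
            "depth_m": depths}))
        rows.append(pd.DataFrame({
            "trawl_id": ids[ti], "year": year, "lat": locs[ti, 1],
            "lon": locs[ti, 0], "depth_m": depths[ti],
            "species": np.asarray(codes)[si], "biomass_kg": catch[ti, si]}))
        tid += n_t

    df = pd.concat(rows, ignore_index=True)
    tows = pd.concat(tow_records, ignore_index=True)
    table = TrawlTable(df, species_list=codes,
                       year_range=(int(years[0]), int(years[-1])), trawls=tows)

    traits = sp[["body_length_cm", "doubling_time", "trophic_level",
                 "vertical_position", "aggregation", "food_niche"]].copy()

    # --- ground truth on noiseless expectations
    mean_log_kernel = log_kernel_p.mean(axis=0)
    exp_log_catch = logB_true + mean_log_kernel[None, :]
    post = years >= GEAR_CHANGE_YEAR
    exp_log_catch = exp_log_catch + post[:, None] * np.log(gear)[None, :]
    lb = pd.DataFrame(logB_true, index=years, columns=codes)
    elc = pd.DataFrame(exp_log_catch, index=years, columns=codes)
    from .synchrony import community_synchrony
    window = 5
    recs = []
    eB = np.exp(exp_log_catch)
    import warnings as _warnings
    for end in range(window - 1, n_years):
        with _warnings.catch_warnings():
            # constant noiseless windows (stable phase) have undefined phi
            _warnings.simplefilter("ignore")
            phi = community_synchrony(eB[end - window + 1: end + 1])
        recs.append({"window_end_year": int(years[end]), "phi": phi})
    truth = GroundTruth(
        log_biomass=lb, expected_log_catch=elc,
        presence_rate=pd.DataFrame(presence_rate, index=years, columns=codes),
        true_window_synchrony=pd.DataFrame(recs),
        depth_structuring=float(np.var(log_kernel_p, axis=0).mean()),
        phases=cfg.phases)
    return table, traits, polys, truth
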