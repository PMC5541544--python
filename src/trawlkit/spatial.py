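"""Spatial structure of the community: polygons, clustering, distance-decay.

The survey domain is partitioned into Voronoi polygons; trawls are pooled
within polygons so that community composition can be compared across space.
Two spatial indicators are computed per year: the variance in between-polygon
compositional dissimilarity explained by geographic distance and by depth
difference (distance-decay regression on logit dissimilarity), and hierarchical
community-type clusters over polygon-period averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint, Point, Polygon, shape
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .datatypes import CommunityMatrix, TrawlTable

__all__ = [
    "PolygonSet",
    "ClusterAssignment",
    "VariancePartition",
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "build_voronoi_polygons",
    "assign_trawls",
    "polygon_mean_depths",
    "retain_consistent_polygons",
    "complete_linkage",
    "cut_tree",
    "cluster_polygon_periods",
    "cluster_profiles",
    "partition_dissimilarity",
    "variance_partition_by_year",
    "diversity_diagnostics",
]

#: Mean Earth radius (km) for great-circle distances.
EARTH_RADIUS_KM = 6371.0088


@dataclass
class PolygonSet:
    """A planar partition of the survey domain.

    ``table`` has one row per polygon: polygon_id, geometry (shapely Polygon),
    centroid_lon/lat, mean_depth_m (NaN until observed depths are attached)
    and years_present (set of survey years with >= 1 trawl).
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = ["polygon_id", "geometry"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"polygon table missing column(s): {missing}")
        t = self.table.copy()
        if "centroid_lon" not in t.columns:
            cents = [g.centroid for g in t["geometry"]]
            t["centroid_lon"] = [c.x for c in cents]
            t["centroid_lat"] = [c.y for c in cents]
        if "mean_depth_m" not in t.columns:
            t["mean_depth_m"] = np.nan
        if "years_present" not in t.columns:
            t["years_present"] = [set() for _ in range(len(t))]
        self.table = t.reset_index(drop=True)

    @property
    def ids(self) -> list:
        return self.table["polygon_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, keep_ids) -> "PolygonSet":
        keep = set(keep_ids)
        sub = self.table[self.table["polygon_id"].isin(keep)].reset_index(drop=True)
        return PolygonSet(sub)

    def centroids(self) -> np.ndarray:
        return self.table[["centroid_lon", "centroid_lat"]].to_numpy(dtype=float)

    def depths(self) -> np.ndarray:
        return self.table["mean_depth_m"].to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    """Community-type cluster labels for polygon-period units."""

    assignments: pd.DataFrame  # columns: unit, cluster, linkage_height
    merge_tree: np.ndarray  # (n-1, 4) linkage-style matrix
    k: int = 0

    def __post_init__(self):
        labels = self.assignments["cluster"].unique()
        if self.k and len(labels) != self.k:
            raise ValueError(f"expected exactly {self.k} clusters, found {len(labels)}")


@dataclass
class VariancePartition:
    """Per-year distance-decay decomposition of compositional dissimilarity."""

    year: int
    r2_distance: float  # adjusted partial R^2 of geographic distance
    r2_depth: float  # adjusted partial R^2 of depth difference
    r2_full: float  # adjusted R^2 of the two-predictor model
    n_pairs: int


# ---------------------------------------------------------------------------
# Geometry


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance on a spherical Earth, in km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def build_voronoi_polygons(seeds: np.ndarray, boundary: Polygon) -> PolygonSet:
    """Voronoi partition of ``boundary`` around seed points (lon, lat).

    Cells are clipped to the boundary; each seed lies inside its own cell.
    Polygon ids follow seed order.
    """
    seeds = np.asarray(seeds, dtype=float)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed points")
    if len(np.unique(seeds, axis=0)) != len(seeds):
        raise ValueError("duplicate seed points")
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=boundary)
    # voronoi_diagram does not preserve seed order: match cells back to seeds
    tree = STRtree(list(cells.geoms))
    rows = []
    for i, p in enumerate(seeds):
        pt = Point(p)
        hit = None
        for j in tree.query(pt):
            if cells.geoms[int(j)].covers(pt):
                hit = cells.geoms[int(j)]
                break
        if hit is None:  # pragma: no cover - degenerate geometry
            raise RuntimeError(f"no Voronoi cell covers seed {i}")
        clipped = hit.intersection(boundary)
        rows.append({"polygon_id": i, "geometry": clipped,
                     "seed_lon": p[0], "seed_lat": p[1]})
    return PolygonSet(pd.DataFrame(rows))


def assign_trawls(table: TrawlTable, polys: PolygonSet,
                  on_outside: str = "drop") -> TrawlTable:
    """Annotate each tow with its polygon id by point-in-polygon.

    Returns a new TrawlTable whose tow index and records carry a polygon_id
    column.  A point on a shared boundary is assigned to the adjacent cell
    with the lowest polygon id (deterministic tie rule).  Tows outside all
    cells are dropped with a warning (default) or raise when
    ``on_outside='error'``.
    """
    idx = table.trawl_index()
    geoms = list(polys.table["geometry"])
    pids = np.asarray(polys.ids)
    tree = STRtree(geoms)
    pts = [Point(lon, lat) for lon, lat in zip(idx["lon"], idx["lat"])]
    assigned = np.full(len(pts), -1, dtype=int)
    for i, pt in enumerate(pts):
        cand = sorted(int(j) for j in tree.query(pt))
        hits = [pids[j] for j in cand if geoms[j].covers(pt)]
        if hits:
            assigned[i] = min(hits)
    outside = assigned < 0
    if outside.any():
        msg = f"{outside.sum()} tow(s) fall outside all polygons"
        if on_outside == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", stacklevel=2)
    tows = idx.copy()
    tows["polygon_id"] = assigned
    tows = tows[tows["polygon_id"] >= 0].reset_index(drop=True)
    mapping = tows.set_index("trawl_id")["polygon_id"]
    df = table.df.copy()
    df["polygon_id"] = df["trawl_id"].map(mapping)
    df = df[df["polygon_id"].notna()].reset_index(drop=True)
    df["polygon_id"] = df["polygon_id"].astype(int)
    return TrawlTable(df, species_list=table.species_list,
                      year_range=table.year_range, trawls=tows)


def polygon_mean_depths(table: TrawlTable, polys: PolygonSet) -> PolygonSet:
    """Attach arithmetic-mean observed tow depth and years present per polygon."""
    tows = table.trawls
    if "polygon_id" not in tows.columns:
        raise ValueError("table has no polygon assignments; run assign_trawls first")
    depth = tows.groupby("polygon_id")["depth_m"].mean()
    years = tows.groupby("polygon_id")["year"].agg(lambda s: set(int(y) for y in s))
    t = polys.table.copy()
    t["mean_depth_m"] = t["polygon_id"].map(depth)
    t["years_present"] = t["polygon_id"].map(years).apply(
        lambda v: v if isinstance(v, set) else set())
    return PolygonSet(t)


def retain_consistent_polygons(polys: PolygonSet, min_years: int,
                               total_years: int | None = None) -> PolygonSet:
    """Keep polygons sampled in at least ``min_years`` survey years."""
    counts = polys.table["years_present"].apply(len)
    if total_years is not None and min_years > total_years:
        raise ValueError("min_years exceeds total_years")
    return polys.subset(polys.table.loc[counts >= min_years, "polygon_id"])


# ---------------------------------------------------------------------------
# Community-type clustering

def complete_linkage(d: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage clustering of a square dissimilarity matrix.

    Returns a linkage-style matrix with one row per merge:
    (cluster_a, cluster_b, height, new_size), where clusters 0..n-1 are the
    original units and cluster n+k is the one formed at merge k.  Ties in the
    minimum inter-cluster distance are broken by the smallest pair of
    representative unit indices, so the merge order is fully deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    cluster_id = np.arange(n)  # scipy-style id of the cluster represented at slot i
    size = np.ones(n, dtype=int)
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = int(np.argmin(sub))  # row-major => smallest (i, j) among ties
        k = sub.shape[0]
        i_s, j_s = divmod(flat, k)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        act_idx = np.flatnonzero(active)
        i, j = int(act_idx[i_s]), int(act_idx[j_s])
        h = work[i, j]
        merges[step] = (cluster_id[i], cluster_id[j], h, size[i] + size[j])
        # complete linkage: distance to merged cluster is the max of the parts
        new_row = np.maximum(work[i], work[j])
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        cluster_id[i] = n + step
        size[i] += size[j]
    return merges


def cut_tree(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Labels (0..k-1) from the first n-k merges of a linkage matrix."""
    if k > n:
        raise ValueError("k exceeds number of units")
    parent = np.arange(n + len(merges))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def cluster_polygon_periods(cm: CommunityMatrix, k: int) -> ClusterAssignment:
    """Community-type clusters over polygon-period units.

    Complete-linkage clustering of Bray-Curtis dissimilarities between
    relative-biomass rows, cut to exactly ``k`` groups.  Labels are
    canonicalized by descending share of each cluster's single most abundant
    species (cluster 1 = most dominated), a stable relabeling.
    """
    from .composition import bray_curtis  # local import avoids a cycle

    units = cm.row_labels
    n = len(units)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} units")
    dm = bray_curtis(cm)
    merges = complete_linkage(dm.values)
    labels = cut_tree(merges, n, k)

    # stable canonical labels: order clusters by max mean relative-biomass share
    rows = cm.values
    sums = rows.sum(axis=1, keepdims=True)
    rel = np.divide(rows, sums, out=np.zeros_like(rows), where=sums > 0)
    order_keys = []
    for lab in range(labels.max() + 1):
        mask = labels == lab
        prof = rel[mask].mean(axis=0)
        order_keys.append((-prof.max(), int(np.flatnonzero(mask)[0])))
    rank = {lab: r + 1 for r, lab in
            enumerate(sorted(range(labels.max() + 1), key=lambda l: order_keys[l]))}
    canon = np.array([rank[l] for l in labels])

    # height at which each unit's cluster was completed
    heights = np.zeros(n)
    member = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        mem = member.pop(a) + member.pop(b)
        member[n + step] = mem
        for u in mem:
            heights[u] = merges[step, 2]

    out = pd.DataFrame({"unit": units, "cluster": canon, "linkage_height": heights})
    return ClusterAssignment(out, merges, k=k)


def cluster_profiles(assignment: ClusterAssignment, cm: CommunityMatrix,
                     focal_species: list) -> pd.DataFrame:
    """Mean relative composition per cluster, for focal species plus 'other'."""
    rows = cm.values
    sums = rows.sum(axis=1, keepdims=True)
    rel = np.divide(rows, sums, out=np.zeros_like(rows), where=sums > 0)
    rel = pd.DataFrame(rel, index=cm.row_labels, columns=cm.species)
    lab = assignment.assignments.set_index("unit")["cluster"]
    rel["cluster"] = [lab[u] for u in rel.index]
    prof = rel.groupby("cluster").mean()
    focal = [s for s in focal_species if s in prof.columns]
    out = prof[focal].copy()
    out["other"] = 1.0 - out.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Distance-decay variance partitioning


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return 1.0 - np.sum(resid**2) / tss


def partition_dissimilarity(bc: np.ndarray, depth_diff: np.ndarray,
                            dist_km: np.ndarray, *, year: int = 0,
                            eps: float = 1e-4, eps_depth: float = 1e-3,
                            eps_dist: float = 1e-3,
                            log_depth: bool = True,
                            log_dist: bool = True) -> VariancePartition:
    """Partial adjusted R^2 of depth and distance for pairwise dissimilarity.

    Response is logit(BC) with BC clamped to [eps, 1-eps]; predictors are
    ln(|depth difference| + eps_depth) and ln(distance + eps_dist) (log
    transforms individually switchable).  Partial adjusted R^2 of X given Z is
    adjR2(X+Z) - adjR2(Z); polygon pairs are treated as independent
    observations.
    """
    bc = np.asarray(bc, dtype=float)
    y = np.log(np.clip(bc, eps, 1 - eps) / (1 - np.clip(bc, eps, 1 - eps)))
    xd = np.abs(np.asarray(depth_diff, dtype=float))
    xg = np.asarray(dist_km, dtype=float)
    xd = np.log(xd + eps_depth) if log_depth else xd
    xg = np.log(xg + eps_dist) if log_dist else xg
    n = len(y)
    if np.allclose(y, y[0]):
        warnings.warn("constant dissimilarity response; R^2 set to zero", stacklevel=2)
        return VariancePartition(year, 0.0, 0.0, 0.0, n)
    a_full = _adj_r2(_ols_r2(y, np.column_stack([xg, xd])), n, 2)
    a_dist = _adj_r2(_ols_r2(y, xg[:, None]), n, 1)
    a_depth = _adj_r2(_ols_r2(y, xd[:, None]), n, 1)
    return VariancePartition(year, a_full - a_depth, a_full - a_dist, a_full, n)


def variance_partition_by_year(cm: CommunityMatrix, polys: PolygonSet, year: int,
                               **kwargs) -> VariancePartition:
    """Distance-decay partition for one survey year.

    ``cm`` must be a polygon-year matrix with row labels (polygon_id, year),
    normalized rows.  Uses great-circle distances between polygon centroids
    and absolute differences of polygon mean depths.
    """
    rows = [r for r in cm.row_labels if r[1] == year]
    if len(rows) < 4:
        raise ValueError(f"need >= 4 polygons present in {year}, found {len(rows)}")
    pids = [r[0] for r in rows]
    meta = polys.table.set_index("polygon_id").loc[pids]
    sub = cm.data.loc[rows].to_numpy(dtype=float)
    bc = pdist(sub, metric="braycurtis")
    depths = meta["mean_depth_m"].to_numpy(dtype=float)
    lats = meta["centroid_lat"].to_numpy(dtype=float)
    lons = meta["centroid_lon"].to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(pids), k=1)
    ddepth = np.abs(depths[ii] - depths[jj])
    dist = great_circle_km(lats[ii], lons[ii], lats[jj], lons[jj])
    return partition_dissimilarity(bc, ddepth, dist, year=year, **kwargs)


def diversity_diagnostics(cm: CommunityMatrix, table: TrawlTable) -> pd.DataFrame:
    """Annual alpha diversity and between-polygon dissimilarity summaries.

    alpha = mean per-tow species richness (species with positive biomass per
    tow, averaged within year); dissimilarity mean/variance are taken over the
    off-diagonal Bray-Curtis entries between polygons present that year
    (sample variance).
    """
    pos = table.df[table.df["biomass_kg"] > 0]
    richness = pos.groupby("trawl_id")["species"].nunique()
    # tows that caught nothing still count, with richness zero
    tows = table.trawls
    per_tow = tows["trawl_id"].map(richness).fillna(0.0)
    alpha = per_tow.groupby(tows["year"].to_numpy()).mean()

    years = sorted(alpha.index)
    recs = []
    for y in years:
        rows = [r for r in cm.row_labels if r[1] == y]
        if len(rows) >= 2:
            bc = pdist(cm.data.loc[rows].to_numpy(dtype=float), metric="braycurtis")
            mean_d, var_d = float(np.mean(bc)), float(np.var(bc, ddof=1)) if len(bc) > 1 else 0.0
        else:
            mean_d, var_d = np.nan, np.nan
        recs.append({"year": y, "alpha": float(alpha[y]),
                     "mean_dissimilarity": mean_d, "var_dissimilarity": var_d})
    return pd.DataFrame(recs)


def polygons_from_geojson(obj) -> PolygonSet:
    """Build a PolygonSet from a GeoJSON FeatureCollection mapping."""
    rows = []
    for feat in obj["features"]:
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        rows.append({"polygon_id": props["polygon_id"], "geometry": geom,
                     "mean_depth_m": props.get("mean_depth_m", np.nan)})
    return PolygonSet(pd.DataFrame(rows))


def polygons_to_geojson(polys: PolygonSet) -> dict:
    """Serialize a PolygonSet to a GeoJSON FeatureCollection mapping."""
    feats = []
    for _, row in polys.table.iterrows():
        props = {"polygon_id": int(row["polygon_id"])}
        if np.isfinite(row["mean_depth_m"]):
            props["mean_depth_m"] = float(row["mean_depth_m"])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": row["geometry"].__geo_interface__})
    return {"type": "FeatureCollection", "features": feats}
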