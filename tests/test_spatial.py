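"""Polygons, clustering, distance-decay regression and diversity diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Point, box

from trawlkit import (CommunityMatrix, build_voronoi_polygons, assign_trawls,
                      cluster_polygon_periods, cluster_profiles,
                      complete_linkage, great_circle_km,
                      partition_dissimilarity, retain_consistent_polygons)
from trawlkit.spatial import PolygonSet, cut_tree, diversity_diagnostics
from conftest import make_table


class TestGreatCircle:
    def test_limits(self):
        assert great_circle_km(47.0, -52.0, 47.0, -52.0) == 0.0
        half = great_circle_km(0.0, 0.0, 0.0, 180.0)
        assert half == pytest.approx(np.pi * 6371.0088, rel=1e-9)

    def test_symmetry_and_triangle(self, rng):
        pts = rng.uniform([-60, 40], [-40, 60], size=(30, 2))
        for _ in range(50):
            i, j, k = rng.choice(30, 3, replace=False)
            dij = great_circle_km(pts[i, 1], pts[i, 0], pts[j, 1], pts[j, 0])
            dji = great_circle_km(pts[j, 1], pts[j, 0], pts[i, 1], pts[i, 0])
            assert dij == pytest.approx(dji, rel=1e-12)
            dik = great_circle_km(pts[i, 1], pts[i, 0], pts[k, 1], pts[k, 0])
            dkj = great_circle_km(pts[k, 1], pts[k, 0], pts[j, 1], pts[j, 0])
            assert dij <= dik + dkj + 1e-9


class TestVoronoi:
    def test_four_symmetric_seeds(self):
        boundary = box(0, 0, 2, 2)
        seeds = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
        polys = build_voronoi_polygons(seeds, boundary)
        areas = [g.area for g in polys.table["geometry"]]
        np.testing.assert_allclose(areas, 1.0, rtol=1e-9)
        assert sum(areas) == pytest.approx(boundary.area, rel=1e-6)
        for (x, y), g in zip(seeds, polys.table["geometry"]):
            assert g.covers(Point(x, y))

    def test_random_seeds_partition(self, rng):
        boundary = box(-55, 46, -48, 55)
        seeds = np.column_stack([rng.uniform(-55, -48, 20), rng.uniform(46, 55, 20)])
        polys = build_voronoi_polygons(seeds, boundary)
        assert sum(g.area for g in polys.table["geometry"]) == pytest.approx(
            boundary.area, rel=1e-6)
        for (x, y), g in zip(seeds, polys.table["geometry"]):
            assert g.covers(Point(x, y))

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError):
            build_voronoi_polygons(np.array([[0, 0], [0, 0], [1, 1]]),
                                   box(-1, -1, 2, 2))


class TestAssignTrawls:
    def _polys(self):
        return PolygonSet(pd.DataFrame({
            "polygon_id": [0, 1],
            "geometry": [box(-53, 46, -52, 48), box(-52, 46, -51, 48)]}))

    def test_point_in_cell_and_outside_dropped(self):
        t = make_table([("a", 1990, 47.0, -52.5, 100, "cod", 1.0),
                        ("b", 1990, 47.0, -51.5, 100, "cod", 1.0),
                        ("c", 1990, 47.0, -40.0, 100, "cod", 1.0)])
        with pytest.warns(UserWarning, match="outside"):
            out = assign_trawls(t, self._polys())
        got = out.trawls.set_index("trawl_id")["polygon_id"]
        assert got["a"] == 0 and got["b"] == 1 and "c" not in got.index

    def test_boundary_tie_goes_to_lowest_id(self):
        t = make_table([("x", 1990, 47.0, -52.0, 100, "cod", 1.0)])
        out = assign_trawls(t, self._polys())
        assert out.trawls["polygon_id"].iloc[0] == 0

    def test_counts_match_brute_force(self, small_survey):
        table, _, polys, _ = small_survey
        sub = make_table(
            table.df[table.df["year"] == 1981].head(300)
            [["trawl_id", "year", "lat", "lon", "depth_m", "species",
              "biomass_kg"]].values.tolist())
        out = assign_trawls(sub, polys)
        counts = out.trawls["polygon_id"].value_counts()
        brute = {}
        for _, row in sub.trawls.iterrows():
            pt = Point(row["lon"], row["lat"])
            hits = [pid for pid, g in zip(polys.ids, polys.table["geometry"])
                    if g.covers(pt)]
            if hits:
                brute[row["trawl_id"]] = min(hits)
        brute_counts = pd.Series(brute).value_counts()
        assert counts.sort_index().equals(brute_counts.sort_index())


def test_retain_consistent_polygons():
    t = pd.DataFrame({"polygon_id": [0, 1, 2],
                      "geometry": [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1)],
                      "years_present": [set(range(1981, 2014)),
                                        set(range(1981, 1991)),
                                        set(range(1981, 2012))]})
    polys = PolygonSet(t)
    kept = retain_consistent_polygons(polys, 30, 33)
    assert kept.ids == [0, 2]


class TestCompleteLinkage:
    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(20):
            d = squareform(rng.uniform(0.05, 1.0, 45))  # 10 units, no ties
            ours = complete_linkage(d)
            ref = linkage(squareform(d, checks=False), method="complete")
            np.testing.assert_allclose(ours[:, 2], ref[:, 2], atol=1e-12)
            for row_o, row_r in zip(ours, ref):
                assert {row_o[0], row_o[1]} == {row_r[0], row_r[1]}

    def test_heights_non_decreasing(self, rng):
        d = squareform(rng.uniform(0, 1, 66))
        merges = complete_linkage(d)
        assert np.all(np.diff(merges[:, 2]) >= -1e-12)

    def test_cut_tree_extremes(self, rng):
        d = squareform(rng.uniform(0, 1, 28))  # 8 units
        merges = complete_linkage(d)
        assert len(np.unique(cut_tree(merges, 8, 8))) == 8
        assert len(np.unique(cut_tree(merges, 8, 1))) == 1


class TestClusterPolygonPeriods:
    def _blob_matrix(self, rng):
        a = np.abs(rng.normal([10, 1, 0.5], 0.05, (4, 3)))
        b = np.abs(rng.normal([0.5, 1, 10], 0.05, (4, 3)))
        mat = pd.DataFrame(np.vstack([a, b]),
                           index=[(i, (2000, 2004)) for i in range(8)],
                           columns=["x", "y", "z"])
        sums = mat.sum(axis=1)
        return CommunityMatrix(mat.div(sums, axis=0), normalized=True)

    def test_two_blobs_separate(self, rng):
        cm = self._blob_matrix(rng)
        out = cluster_polygon_periods(cm, 2)
        labels = out.assignments["cluster"].to_numpy()
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_singletons(self, rng):
        cm = self._blob_matrix(rng)
        out = cluster_polygon_periods(cm, 8)
        assert out.assignments["cluster"].nunique() == 8

    def test_k_exceeds_units(self, rng):
        with pytest.raises(ValueError):
            cluster_polygon_periods(self._blob_matrix(rng), 9)

    def test_row_order_invariance(self, rng):
        cm = self._blob_matrix(rng)
        perm = rng.permutation(8)
        cm2 = CommunityMatrix(cm.data.iloc[perm], normalized=True)
        out1 = cluster_polygon_periods(cm, 2).assignments.set_index("unit")["cluster"]
        out2 = cluster_polygon_periods(cm2, 2).assignments.set_index("unit")["cluster"]
        assert out1.sort_index().equals(out2.sort_index())

    def test_profiles(self, rng):
        cm = self._blob_matrix(rng)
        out = cluster_polygon_periods(cm, 2)
        prof = cluster_profiles(out, cm, ["x"])
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        lab = out.assignments.set_index("unit")["cluster"]
        for cl in (1, 2):
            members = [u for u in lab.index if lab[u] == cl]
            rel = cm.data.loc[members, "x"]
            assert prof.loc[cl, "x"] == pytest.approx(rel.mean(), rel=1e-9)


class TestVariancePartition:
    def test_depth_only_construction(self, rng):
        n = 15
        depths = rng.uniform(50, 500, n)
        lon = rng.uniform(-55, -48, n)
        lat = rng.uniform(46, 55, n)
        ii, jj = np.triu_indices(n, k=1)
        ddepth = np.abs(depths[ii] - depths[jj])
        dist = great_circle_km(lat[ii], lon[ii], lat[jj], lon[jj])
        # logit(BC) exactly linear in ln(ddepth + eps), zero noise
        logit_bc = -2.0 + 0.5 * np.log(ddepth + 1e-3)
        bc = 1 / (1 + np.exp(-logit_bc))
        vp = partition_dissimilarity(bc, ddepth, dist)
        assert vp.r2_depth > 0.95
        assert abs(vp.r2_distance) < 0.05
        assert vp.n_pairs == n * (n - 1) // 2

    def test_permuted_response_null(self, rng):
        n = 15
        depths = rng.uniform(50, 500, n)
        lon, lat = rng.uniform(-55, -48, n), rng.uniform(46, 55, n)
        ii, jj = np.triu_indices(n, k=1)
        ddepth = np.abs(depths[ii] - depths[jj])
        dist = great_circle_km(lat[ii], lon[ii], lat[jj], lon[jj])
        fulls = []
        for _ in range(30):
            bc = rng.uniform(0.1, 0.9, len(ii))
            vp = partition_dissimilarity(bc, ddepth, dist)
            fulls.append(vp.r2_full)
        assert abs(np.mean(fulls)) < 0.03

    def test_constant_response_zeroes(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            vp = partition_dissimilarity(np.full(10, 0.5), rng.uniform(1, 5, 10),
                                         rng.uniform(1, 5, 10))
        assert vp.r2_full == 0.0


class TestDiversityDiagnostics:
    def test_toy_year(self):
        rows = []
        for tid, species in [("t1", ["a", "b", "c"]), ("t2", ["a", "b", "c"]),
                             ("t3", ["a", "b", "c"])]:
            for sp in species:
                rows.append((tid, 2000, 47.0, -52.0, 100.0, sp, 1.0))
        table = make_table(rows)
        comp = pd.DataFrame([[0.6, 0.4, 0.0], [0.2, 0.4, 0.4], [0.5, 0.25, 0.25]],
                            index=[(0, 2000), (1, 2000), (2, 2000)],
                            columns=["a", "b", "c"])
        cm = CommunityMatrix(comp, normalized=True)
        out = diversity_diagnostics(cm, table)
        assert out.loc[0, "alpha"] == pytest.approx(3.0)  # all tows catch all
        from trawlkit import bray_curtis_pair as bcp
        vals = [bcp(comp.iloc[0], comp.iloc[1]), bcp(comp.iloc[0], comp.iloc[2]),
                bcp(comp.iloc[1], comp.iloc[2])]
        assert out.loc[0, "mean_dissimilarity"] == pytest.approx(np.mean(vals))
        assert out.loc[0, "var_dissimilarity"] == pytest.approx(np.var(vals, ddof=1))

    def test_identical_compositions_zero(self):
        table = make_table([("t1", 2000, 47.0, -52.0, 100.0, "a", 1.0)])
        comp = pd.DataFrame([[0.5, 0.5]] * 3,
                            index=[(0, 2000), (1, 2000), (2, 2000)],
                            columns=["a", "b"])
        out = diversity_diagnostics(CommunityMatrix(comp, normalized=True), table)
        assert out.loc[0, "mean_dissimilarity"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "var_dissimilarity"] == pytest.approx(0.0, abs=1e-12)
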