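"""Gower dissimilarity, PCoA embedding and functional dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from trawlkit import (CommunityMatrix, DissimilarityMatrix, TraitSpace,
                      annual_fdis, community_weighted_trait_means, fdis,
                      gower_dissimilarity, pcoa_embed)


def _traits(rows):
    cols = ["species", "vertical_position", "body_length_cm", "doubling_time",
            "trophic_level", "aggregation", "food_niche"]
    return pd.DataFrame(rows, columns=cols)


class TestGower:
    def test_identical_rows_zero(self):
        t = _traits([("a", "demersal", 50, 4, 3.5, "solitary", "piscivore"),
                     ("b", "demersal", 50, 4, 3.5, "solitary", "piscivore")])
        d = gower_dissimilarity(t)
        assert d.values[0, 1] == 0.0

    def test_maximally_different_is_one(self):
        t = _traits([("a", "demersal", 10, 1, 2.0, "solitary", "piscivore"),
                     ("b", "pelagic", 100, 9, 4.5, "schooling", "benthivore")])
        d = gower_dissimilarity(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_three_species_hand_values(self):
        t = _traits([("a", "demersal", 10, 2, 3.0, "solitary", "piscivore"),
                     ("b", "pelagic", 30, 2, 4.0, "solitary", "benthivore"),
                     ("c", "demersal", 20, 4, 3.0, "schooling", "piscivore")])
        d = gower_dissimilarity(t).to_frame()
        # a-b: length |10-30|/20=1, doubling 0, trophic 1, vert 1, agg 0, food 1
        assert d.loc["a", "b"] == pytest.approx(4 / 6)
        # a-c: length 0.5, doubling 1, trophic 0, vert 0, agg 1, food 0
        assert d.loc["a", "c"] == pytest.approx(2.5 / 6)
        # b-c: length 0.5, doubling 1, trophic 1, vert 1, agg 1, food 1
        assert d.loc["b", "c"] == pytest.approx(5.5 / 6)

    def test_zero_range_trait_dropped(self):
        t = _traits([("a", "demersal", 10, 3, 3.0, "solitary", "piscivore"),
                     ("b", "pelagic", 20, 3, 4.0, "schooling", "benthivore")])
        with pytest.warns(UserWarning, match="doubling_time"):
            d = gower_dissimilarity(t)
        assert d.values[0, 1] == pytest.approx(1.0)  # 5 informative traits, all maximal


class TestPCoA:
    def test_points_on_a_line(self):
        x = np.array([0.0, 0.3, 0.7, 1.0])
        d = DissimilarityMatrix(list("abcd"), np.abs(x[:, None] - x[None, :]))
        space = pcoa_embed(d)
        assert space.correction == "none"
        # one dominant axis reproducing the spacing up to sign
        rec = squareform(pdist(space.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-8)
        assert space.coordinates.shape[1] == 1

    def test_euclidean_input_uncorrected(self, rng):
        pts = rng.normal(0, 1, (6, 3))
        d = squareform(pdist(pts))
        space = pcoa_embed(DissimilarityMatrix(range(6), d / (d.max() * 1.01)))
        assert space.correction == "none"

    def test_matches_skbio_on_euclidean_input(self, rng):
        # independent implementation check on a Euclidean matrix (where no
        # correction is involved): embedded distances must agree
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(0, 1, (7, 3))
        d = squareform(pdist(pts))
        d = d / (d.max() * 1.01)
        ours = pcoa_embed(DissimilarityMatrix(range(7), d))
        ref = skbio_pcoa(d, number_of_dimensions=3)
        np.testing.assert_allclose(
            squareform(pdist(ours.coordinates)),
            squareform(pdist(ref.samples.to_numpy()[:, :3])), atol=1e-8)

    def test_gower_reconstruction_after_correction(self, rng):
        rows = []
        for i in range(6):
            rows.append((f"s{i}", rng.choice(["d", "p", "bd"]),
                         float(rng.uniform(10, 100)), float(rng.uniform(1, 9)),
                         float(rng.uniform(2, 4.5)),
                         rng.choice(["sol", "sch"]), rng.choice(["pi", "be", "pl"])))
        d = gower_dissimilarity(_traits(rows))
        space = pcoa_embed(d)
        rec = squareform(pdist(space.coordinates))
        target = d.values.copy()
        if space.correction == "cailliez":
            # corrected distances: original plus the Cailliez constant off-diagonal
            off = ~np.eye(len(target), dtype=bool)
            c = rec[off].mean() - target[off].mean()
            target[off] += c
        np.testing.assert_allclose(rec, target, atol=1e-8)


class TestFDis:
    def _two_point_space(self):
        return TraitSpace(["a", "b"], np.array([[0.0], [1.0]]), "none", 0.0)

    def test_single_species_zero(self):
        space = self._two_point_space()
        assert fdis(space, [1.0, 0.0]) == 0.0

    def test_two_species_closed_forms(self):
        space = self._two_point_space()
        assert fdis(space, [0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
        assert fdis(space, [0.75, 0.25]) == pytest.approx(0.375, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        for _ in range(25):
            X = rng.normal(0, 1, (8, 4))
            a = rng.uniform(0, 1, 8)
            space = TraitSpace(list("abcdefgh"), X, "none", 0.0)
            w = a / a.sum()
            c = sum(w[j] * X[j] for j in range(8))
            expect = sum(w[j] * np.sqrt(((X[j] - c) ** 2).sum()) for j in range(8))
            assert fdis(space, a) == pytest.approx(expect, abs=1e-10)

    def test_invariances(self, rng):
        X = rng.normal(0, 1, (5, 3))
        a = rng.uniform(0.1, 1, 5)
        space = TraitSpace(list("abcde"), X, "none", 0.0)
        base = fdis(space, a)
        # weight rescaling
        assert fdis(space, 10 * a) == pytest.approx(base, rel=1e-12)
        # rigid rotation
        q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        rot = TraitSpace(list("abcde"), X @ q, "none", 0.0)
        assert fdis(rot, a) == pytest.approx(base, rel=1e-10)
        # adding a zero-weight species
        X6 = np.vstack([X, rng.normal(0, 1, 3)])
        sp6 = TraitSpace(list("abcdef"), X6, "none", 0.0)
        assert fdis(sp6, np.append(a, 0.0)) == pytest.approx(base, rel=1e-12)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            fdis(self._two_point_space(), [0.0, 0.0])


class TestAnnualSeries:
    def test_constant_weights_constant_series(self):
        space = TraitSpace(["a", "b", "c"], np.array([[0.0], [1.0], [2.0]]),
                           "none", 0.0)
        mat = pd.DataFrame(np.ones((4, 3)), index=[2000, 2001, 2002, 2003],
                           columns=["a", "b", "c"])
        series = annual_fdis(CommunityMatrix(mat), space)
        assert np.ptp(series.values) == pytest.approx(0.0, abs=1e-12)

    def test_dominance_limit_zero(self):
        space = TraitSpace(["a", "b"], np.array([[0.0], [1.0]]), "none", 0.0)
        mat = pd.DataFrame([[1e9, 1.0]], index=[2000], columns=["a", "b"])
        series = annual_fdis(CommunityMatrix(mat), space)
        assert series.values[0] < 1e-6


class TestWeightedTraitMeans:
    def test_single_and_equal_weights(self):
        t = _traits([("a", "demersal", 10, 2, 3.0, "solitary", "piscivore"),
                     ("b", "pelagic", 30, 4, 4.0, "schooling", "benthivore")])
        mat = pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=[2000, 2001],
                           columns=["a", "b"])
        out = community_weighted_trait_means(CommunityMatrix(mat), t)
        assert out["numeric"].loc[2000, "body_length_cm"] == pytest.approx(10.0)
        assert out["numeric"].loc[2001, "body_length_cm"] == pytest.approx(20.0)
        for c, shares in out["categorical"].items():
            np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-12)
        assert out["categorical"]["aggregation"].loc[2000, "solitary"] == 1.0
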