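"""The synthetic survey generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from trawlkit import (ScenarioConfig, default_collapse_scenario, simulate_survey,
                      zinf_geometric_mean)
from trawlkit.community import annual_species_samples


def _flat_config(**kw):
    """A no-dynamics scenario: flat driver, no gear effect, no species noise."""
    defaults = dict(
        n_species=6, n_polygons=16, years=(1981, 1992),
        phases=((1981, 1992, "stable", 0.0),),
        trawls_per_year=(300.0, 0.0), min_trawls=50,
        gear_k=0.0, sigma_species_year=0.0, seed=11)
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = ScenarioConfig(n_species=5, n_polygons=10, years=(1981, 1984),
                             phases=((1981, 1984, "stable", 0.0),),
                             trawls_per_year=(60.0, 5.0), seed=3)
        t1, tr1, p1, g1 = simulate_survey(cfg)
        cfg2 = ScenarioConfig(n_species=5, n_polygons=10, years=(1981, 1984),
                              phases=((1981, 1984, "stable", 0.0),),
                              trawls_per_year=(60.0, 5.0), seed=3)
        t2, tr2, p2, g2 = simulate_survey(cfg2)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(g1.log_biomass, g2.log_biomass)


class TestConfigValidation:
    def test_phases_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            ScenarioConfig(years=(1981, 2013),
                           phases=((1981, 1990, "stable", 0.0),
                                   (1992, 2013, "stable", 0.0)))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(sigma_trawl=-0.1)


class TestNullScenario:
    def test_flat_driver_means_stationary(self):
        table, *_ = simulate_survey(_flat_config(sigma_trawl=0.0))
        cm_samples = {sp: annual_species_samples(table, sp)
                      for sp in table.species_list}
        for sp, samples in cm_samples.items():
            est = pd.Series({y: zinf_geometric_mean(v) for y, v in samples.items()})
            if est.mean() < 0.05:  # species essentially undetectable
                continue
            first, second = est.iloc[:6].mean(), est.iloc[6:].mean()
            assert first == pytest.approx(second, rel=0.08)


class TestConvergenceToTruth:
    def test_high_detection_low_noise_recovers_expectation(self):
        base = _flat_config(seed=21)
        base.species = None
        from trawlkit.simulate import default_species_params
        sp_params = default_species_params(6, np.random.default_rng(4))
        # strong detection, high baselines and flat depth niches: presence ~ 1
        # everywhere and no spatial sampling noise from the depth kernel
        sp_params["detection_slope"] = 60.0
        sp_params["baseline_log_biomass"] = np.linspace(4.0, 6.0, len(sp_params))
        sp_params["depth_w"] = 1e6
        cfg = _flat_config(years=(1981, 1982),
                           phases=((1981, 1982, "stable", 0.0),),
                           trawls_per_year=(1000.0, 0.0), sigma_trawl=1e-9,
                           trawl_depth_sd=0.0, seed=21)
        cfg.species = sp_params
        table, _, _, truth = simulate_survey(cfg)
        expect = np.exp(truth.expected_log_catch)
        for sp in table.species_list:
            samples = annual_species_samples(table, sp)
            for y, v in samples.items():
                est = zinf_geometric_mean(v)
                assert est == pytest.approx(expect.loc[y, sp], rel=0.05)


class TestZeroInflation:
    def test_presence_rate_matches_binomial_expectation(self):
        cfg = _flat_config(seed=5)
        table, _, _, truth = simulate_survey(cfg)
        tows_per_year = table.trawls.groupby("year").size()
        pos = table.df[table.df["biomass_kg"] > 0]
        emp = pos.groupby(["year", "species"])["trawl_id"].nunique()
        for y in truth.presence_rate.index:
            n = tows_per_year[y]
            for sp in truth.presence_rate.columns:
                p = truth.presence_rate.loc[y, sp]
                k = emp.get((y, sp), 0)
                se = np.sqrt(p * (1 - p) / n)
                assert abs(k / n - p) < 4.5 * se + 2 / n


@pytest.fixture(scope="module")
def truth_pack():
    cfg = default_collapse_scenario(2)
    _table, traits, _polys, truth = simulate_survey(cfg)
    return cfg, traits, truth


class TestDefaultScenarioTruth:
    """Designed qualitative dynamics, checked on noiseless expectations."""

    def test_biomass_minimum_in_trough_years(self, truth_pack):
        cfg, _, truth = truth_pack
        total = np.exp(truth.expected_log_catch).sum(axis=1)
        d = cfg.driver()
        trough_years = set(d.index[d == d.min()])
        assert total.idxmin() in trough_years

    def test_composition_distance_rises_then_falls(self, truth_pack):
        cfg, _, truth = truth_pack
        from trawlkit import bray_curtis_pair
        # ecological (pre-observation) composition: the gear change adds a
        # one-off jump in *observed* composition that is not part of the
        # designed regime trajectory
        eB = np.exp(truth.log_biomass.to_numpy())
        rel = eB / eB.sum(axis=1, keepdims=True)
        years = truth.log_biomass.index.to_numpy()
        bc = pd.Series([bray_curtis_pair(rel[i], rel[0]) for i in range(len(years))],
                       index=years)
        shift = cfg.phase_years("shifted_regime")
        rec = cfg.phase_years("compositional_recovery") \
            + cfg.phase_years("biomass_growth")
        from scipy.stats import spearmanr
        # rising trend through the shift, with the peak at its end, then a
        # strict decline through recovery
        assert spearmanr(shift, bc.loc[shift]).statistic > 0.7
        assert bc.idxmax() == shift[-1]
        assert np.all(np.diff(bc.loc[rec]) < 0)

    def test_fdis_drops_during_shift(self, truth_pack):
        cfg, traits, truth = truth_pack
        from trawlkit import fdis, gower_dissimilarity, pcoa_embed
        space = pcoa_embed(gower_dissimilarity(traits))
        eB = np.exp(truth.expected_log_catch)
        shift = cfg.phase_years("shifted_regime")
        f = [fdis(space, eB.loc[y].to_numpy()) for y in shift]
        assert f[-1] < f[0]

    def test_true_synchrony_high_in_collapse(self, truth_pack):
        cfg, _, truth = truth_pack
        sync = truth.true_window_synchrony.set_index("window_end_year")["phi"]
        collapse_ends = [y for y in cfg.phase_years("synchronous_decline")
                         if y - 4 in cfg.phase_years("synchronous_decline")]
        assert (sync.loc[collapse_ends] > 0.95).all()
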