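import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trawlkit import ScenarioConfig, TrawlTable, simulate_survey

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced four-phase scenario: 10 species, 25 polygons, ~60 tows/yr."""
    return ScenarioConfig(n_species=10, n_polygons=25, trawls_per_year=(60.0, 8.0),
                          min_trawls=30, seed=7)


@pytest.fixture(scope="session")
def small_survey(small_scenario):
    return simulate_survey(small_scenario)


def make_table(rows, **kwargs):
    """Build a TrawlTable from (trawl_id, year, lat, lon, depth, species, biomass)."""
    df = pd.DataFrame(rows, columns=["trawl_id", "year", "lat", "lon",
                                     "depth_m", "species", "biomass_kg"])
    return TrawlTable(df, **kwargs)


@pytest.fixture
def tiny_table():
    """Two tows x two species over two years, hand-checkable."""
    return make_table([
        ("t1", 1990, 47.0, -52.0, 100.0, "cod", 4.0),
        ("t1", 1990, 47.0, -52.0, 100.0, "plaice", 1.0),
        ("t2", 1990, 47.5, -52.5, 120.0, "cod", 1.0),
        ("t3", 1991, 47.2, -52.2, 110.0, "cod", 2.0),
        ("t4", 1991, 47.6, -52.6, 130.0, "plaice", 3.0),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
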