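"""Annual robust biomass and moving-window community synchrony.

Estimates per-year community biomass with the zero-inflated geometric-mean
estimator (jackknife SEs) and tracks the 5-year moving-window variance-ratio
synchrony with a 999-replicate randomization test.
"""

import warnings

from trawlkit import (default_collapse_scenario, simulate_survey,
                      screen_gear_sensitive_species, build_community_matrix,
                      moving_window_synchrony, zinf_jackknife)
from trawlkit.community import annual_species_samples

warnings.simplefilter("ignore")

table, traits, polys, truth = simulate_survey(default_collapse_scenario(seed=1))
table, excluded = screen_gear_sensitive_species(table)
print(f"species excluded by the gear-sensitivity screen: {excluded or 'none'}")

samples = annual_species_samples(table)  # community total per tow, per year
for year in (1981, 1990, 1994, 2004, 2013):
    r = zinf_jackknife(samples[year])
    print(f"  {year}: {r.estimate:7.2f} +- {r.se:.2f} kg/tow  (n={r.n})")
print("Biomass collapses ~30-fold into the 1994 trough, then grows slowly.")

annual = build_community_matrix(table)
results = moving_window_synchrony(annual.data, window=5,
                                  n_randomizations=999, seed=1)
print("\n5-year window synchrony (phi in [0,1]; p from permutation null):")
for r in results:
    if r.window_end_year in (1986, 1991, 1994, 2000, 2013):
        flag = "*" if r.p_value <= 0.05 else " "
        print(f"  ..{r.window_end_year}: phi={r.phi:.2f} p={r.p_value:.3f}{flag}"
              f" ({r.direction})")
print("Synchrony is high and significant in collapse windows (declining),")
print("and indistinguishable from independent fluctuations in stable ones.")
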