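"""Compositional trajectory: Bray-Curtis distance from baseline and NMDS.

Normalizes annual communities to relative biomass, ordinates the
between-year Bray-Curtis matrix in two dimensions, and scales similarity to
the 1981 baseline into 0-100 recovery units.
"""

import warnings

from trawlkit import (bray_curtis, build_community_matrix, composition_trajectory,
                      default_collapse_scenario, nmds, normalize_rows,
                      screen_gear_sensitive_species, simulate_survey)

warnings.simplefilter("ignore")

table, *_ = simulate_survey(default_collapse_scenario(seed=1))
table, _ = screen_gear_sensitive_species(table)
annual = normalize_rows(build_community_matrix(table))

d = bray_curtis(annual)
ord2 = nmds(d, k=2, n_starts=20, seed=1)
print(f"NMDS stress (Kruskal stress-1): {ord2.stress:.3f}  "
      f"(converged={ord2.converged})")
print("First axis separates pre-collapse from shifted-regime years:")
for y in (1981, 1990, 1994, 2000, 2004, 2013):
    x1, x2 = ord2.coordinates.loc[y]
    print(f"  {y}: ({x1:+.3f}, {x2:+.3f})")

traj = composition_trajectory(annual, reference_year=1981)
print("\nComposition recovery (100 = 1981 composition, 0 = farthest from it):")
for y in (1981, 1994, 2004, 2013):
    print(f"  {y}: {traj.at(y):6.1f}")
print("Composition keeps drifting away after the biomass trough (the regime")
print("shift lags the collapse) and only partially returns by 2013.")
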