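"""Biomass-weighted functional dispersion (FDis) from mixed traits.

Builds the Gower dissimilarity over six mixed-type traits, embeds it with
PCoA (Cailliez-corrected if non-Euclidean) and tracks the abundance-weighted
dispersion of the community in trait space year by year.
"""

import warnings

from trawlkit import (annual_fdis, build_community_matrix,
                      default_collapse_scenario, gower_dissimilarity, pcoa_embed,
                      screen_gear_sensitive_species, simulate_survey)

warnings.simplefilter("ignore")

table, traits, *_ = simulate_survey(default_collapse_scenario(seed=1))
table, _ = screen_gear_sensitive_species(table)

space = pcoa_embed(gower_dissimilarity(traits.loc[table.species_list]))
print(f"trait-space axes: {space.coordinates.shape[1]}  "
      f"correction: {space.correction}  "
      f"negative eigenvalue mass: {space.negative_eigenvalue_mass:.2e}")

annual = build_community_matrix(table)
series = annual_fdis(annual, space)
for y in (1981, 1990, 1995, 2004, 2013):
    print(f"  {y}: FDis = {series.at(y):.3f}")
print("FDis rises as the collapse spreads biomass across species, then")
print("declines through the shifted regime while dominance concentrates on")
print("the trait-central winner, and rebounds during recovery.")
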