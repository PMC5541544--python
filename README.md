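# trawlkit

Community-level indicators for bottom-trawl survey time series.

Single-species stock assessments can miss reorganizations that play out at
the level of the whole community: synchronous multi-species collapses,
regime shifts in composition, loss of functional diversity, and changes in
spatial structure. `trawlkit` computes a complementary suite of indicators
from raw survey records (one row per species per tow, with year, position,
depth and biomass) for ecosystem scientists and fisheries analysts tracking
collapse and recovery of demersal fish communities:

* **Robust biomass** — the zero-inflated geometric-mean estimator
  `E(b) = (m/n)·exp(Σ ln bᵢ / m)` (m positive tows of n), with leave-one-out
  jackknife standard errors over tows;
* **Community synchrony** — the variance-ratio statistic
  `φ = var(Σₛ xₛ) / (Σₛ sd xₛ)²` on 5-year moving windows, with a
  within-window permutation null (999 replicates, add-one p-value);
* **Composition** — Bray–Curtis dissimilarity `Σ|x−y|/Σ(x+y)` of relative
  biomass, 2-D non-metric MDS (Kruskal stress-1, monotone regression +
  majorization), and a 0–100 recovery scaling anchored at the 1981 reference
  value and the series minimum;
* **Functional diversity** — Gower dissimilarity over six mixed-type traits,
  PCoA embedding (Cailliez-corrected), and biomass-weighted functional
  dispersion `FDis = Σ aⱼ‖xⱼ−c‖/Σ aⱼ`;
* **Spatial structure** — Voronoi-polygon aggregation, complete-linkage
  community-type clustering of polygon-period compositions, and per-year
  partitioning of compositional variance between geographic distance and
  depth difference (partial adjusted R² of a logit/log distance-decay
  regression);
* **A synthetic survey generator** — seeded, depth-stratified, zero-inflated
  lognormal catches with four-phase regime dynamics (stable → synchronous
  collapse → shifted regime → recovery) and a 1995 size-dependent
  catchability shift, with the generating parameters exposed as ground truth.

A gear-sensitivity screen (species whose post-1995 mean biomass exceeds 7×
the pre-1995 mean, or absent before 1995, are removed) runs before every
analysis, and all indicators can be computed for the whole community and for
the community excluding the commercially dominant species.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from trawlkit import (AnalysisConfig, default_collapse_scenario,
                      recovery_summary, run_pipeline)

report = run_pipeline(AnalysisConfig(rng_seed=1),
                      scenario=default_collapse_scenario(seed=1))
print(recovery_summary(report, 2013).round(1))
```

```
composition       37.8
total_biomass     10.9
biomass_SP01       4.4
fdis             253.8
```

Each number is a 0–100 recovery score at 2013: 100 means back at the 1981
reference value, 0 at the historical minimum. In this simulated collapse the
community composition has regained ~38% of the ground it lost while total
biomass has regained only ~11% and the once-dominant species ~4% —
composition and functional diversity recover faster than biomass, which is
exactly the ordering of recovery rates the indicator suite is designed to
resolve. Intermediate quantities are available on the report, e.g.
`report.synchrony["all"]` (per-window φ, p-value and direction — φ reaches
0.96 with p = 0.001 in the collapse windows), `report.nmds["all"].stress`
(0.046 for the 2-D ordination of 33 years), and
`report.variance_partition` (depth explains ~12% of between-polygon
compositional variance, distance ~7%).

The scripts in `examples/` walk through each capability separately:
simulation, biomass + synchrony, composition + NMDS, functional dispersion,
spatial structure, and the full pipeline.

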