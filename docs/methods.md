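# Methods

`trawlkit` computes community-level indicators from bottom-trawl survey
records — one row per species caught in one tow, with year, position, depth
and biomass — to characterize how a demersal fish community collapses,
reorganizes and recovers. This note documents the models, the numerical
choices, and what the synthetic validation scenario does and does not show.

## Robust biomass estimation

Catch-per-tow distributions are zero-inflated (most tows miss most species)
and heavy-tailed. All averages therefore use a two-stage estimator: with
`n` tows, `m` of them positive with biomasses `b_i`,

    E(b) = (m/n) · exp( Σ ln b_i / m ),

i.e. the geometric mean of the positive catches scaled by the occupancy
fraction, defined as 0 when `m = 0`. It is scale-equivariant, bounded by the
sample maximum, and far less tail-sensitive than the arithmetic mean.
Standard errors come from a leave-one-out jackknife over tows (the sampling
unit — never over species), `SE² = (n−1)/n · Σ(θ₍ᵢ₎ − θ̄)²`; a closed-form
O(n) path (`zinf_jackknife`) is tested against the generic resampler.
Annual community matrices apply this estimator per (group, species) with
absent tows entering as zeros.

## Gear-change handling

A mid-series gear change (1995) raised catchability of small fish. Two
mitigations are provided:

* **Screening** (always on): a species is dropped when its pooled mean
  biomass over 1995–2000 exceeds 7× its pooled pre-1995 mean (strict
  inequality, with a 1e−12 relative guard so a ratio of exactly 7 survives
  exp/log round-off), or when it was caught in fewer than `min_pre_trawls`
  (default 1) tows before 1995. Era means pool all tows per era rather than
  averaging annual means. Screening is idempotent because each species'
  decision depends only on its own catches and the (preserved) tow index.
* **Conversion factors** (off by default): per-species multipliers
  `exp(shrunken mean log-ratio)` from matched pre/post tow pairs, shrunk
  toward the across-species grand mean by one-way method-of-moments
  empirical-Bayes weights; species with < 3 pairs inherit the grand mean.
  Which tows are matched is caller-supplied.

## Community synchrony

The variance-ratio statistic `φ = var(Σ_s x_s) / (Σ_s sd(x_s))²` with the
population (divide-by-N) variance convention; 1 for proportional
fluctuations, 0 for exactly compensating ones, undefined (NaN) when every
species is constant. It is computed over 5-year trailing windows of the
annual estimates. Significance: each species' values are independently
permuted within the window (marginals preserved exactly), R = 999
replicates, one-sided for high synchrony, add-one rule
`p = (1 + #{φ_null ≥ φ}) / (R + 1)` so p is never 0. Windows are labelled
`increasing`/`declining` by the sign of the least-squares slope of the
community total, and flagged when they straddle the 1994/1995 gear change.
φ is *not* invariant to rescaling a single species (it is abundance
weighted); it is invariant to species relabeling and to all-zero species.

## Composition

Annual communities are normalized to relative biomass; years are compared by
Bray–Curtis dissimilarity `BC = Σ|x−y| / Σ(x+y)` (complement: quantitative
Sørensen similarity). The between-year matrix is ordinated by non-metric MDS
minimizing Kruskal stress-1 with primary (weak-tie) isotonic regression and
Guttman majorization steps; a backtracking safeguard (halving toward the
previous configuration) makes the recorded stress sequence provably
non-increasing even though the stress-1 normalization is not exactly the
majorized quantity. Defaults: 20 random starts plus one classical-MDS start,
300 iterations, tolerance 1e−7 on the relative stress drop. Coordinates are
centred, rotated to principal axes, and identifiable only up to
rotation/reflection — downstream consumers should use distances or stress.
No Wisconsin/sqrt pre-transformations are applied (the input is already
relative biomass).

Recovery is expressed on a 0–100 scale,
`100·(x_t − min x)/(x_ref − min x)`: 100 at the reference-year (1981) value,
0 at the series minimum. The scaling is invariant to positive affine
transformations of the series and errors out when the reference value *is*
the minimum (in the pipeline the FDis scaling is skipped with a warning in
that degenerate case).

## Functional diversity

Six traits — numeric: max body length (cm), population doubling time,
trophic level; categorical: vertical position, aggregation behaviour, food
niche. Doubling time and trophic level are treated as numeric; the other
three as unordered categoricals. Gower dissimilarity averages range-scaled
numeric differences and 0/1 categorical mismatches, with ranges computed
once over the analysis species pool so yearly values are comparable;
zero-range numeric traits are dropped with a warning. The Gower matrix is
embedded by PCoA (double-centred eigendecomposition); when the relative mass
of negative eigenvalues exceeds 1e−8 the Cailliez constant is added to
off-diagonal distances (Cailliez rather than Lingoes, matching common
functional-dispersion practice) and embedded distances then reproduce the
corrected input to 1e−8. Functional dispersion is
`FDis = Σ aⱼ‖xⱼ − c‖ / Σ aⱼ` with `c` the abundance-weighted centroid —
invariant to weight rescaling and rigid rotations, zero iff all weight sits
at one point. In subset analyses (e.g. excluding commercial species) the
trait space is re-embedded from the subset's own pool, which makes "run the
subset" identical to "run on the reduced community". Community-weighted
trait means report weighted means (numeric) and biomass shares per level
(categorical, summing to 1).

## Spatial structure

The survey domain is partitioned into Voronoi polygons (defaults: cells
around configurable seed points, clipped to the domain); tows are assigned
by point-in-polygon with boundary ties going to the lowest polygon id.
Polygon mean depth is the arithmetic mean of observed tow depths. Polygons
sampled in fewer than 30 of the 33 survey years are excluded from the
variance partitioning (the retained set is parameterized as
`min_years/total_years`).

*Community types*: polygon-period communities (periods 1981–84, 85–89,
90–94, 95–2001, 2002–06, 2007–13 — chosen to avoid straddling 1990 or 1995)
are clustered by complete linkage on Bray–Curtis of relative biomass,
implemented as a vectorized Lance–Williams update with ties broken by the
smallest pair of representative unit indices (fully deterministic; verified
against an O(n³) enumeration and scipy). The tree is cut to exactly K = 7
groups and labels are canonicalized by descending share of each cluster's
most abundant species.

*Distance decay*: per year, for all retained polygon pairs, the response is
`logit(BC)` with BC clamped to [1e−4, 1−1e−4]; predictors are
`ln(|Δdepth| + 1e−3)` and `ln(great-circle km + 1e−3)` (log transforms
individually switchable; great-circle on a sphere of radius 6371.0088 km).
Partial adjusted R² of X given Z is `adjR²(X+Z) − adjR²(Z)` with the
small-sample correction `1 − (1−R²)(n−1)/(n−p−1)`. Pairs are treated as
independent observations; no Mantel-style correction is applied. Adjusted R²
can decrease when predictors are added; only the unadjusted R² is monotone.

*Diagnostics*: alpha diversity is mean per-tow species richness (an explicit
choice; other alpha metrics would serve); between-polygon dissimilarity
mean and sample variance are taken over the off-diagonal Bray–Curtis entries
per year.

## Drivers

Fishing effort is `Σ tonnage × days-at-sea` per year over vessels targeting
benthic fish (tonne-days). The climate index z-scores each component over a
1981–2010 baseline, signs them so negative = colder, and sums; smoothing is
a trailing 5-year moving average (trailing chosen for consistency with the
synchrony window; configurable).

## The synthetic survey generator

The generator emulates the statistical structure the indicators assume, with
ground truth exposed for recovery tests. Regional dynamics:
`log B_{s,t} = baseline_s + γ_s D_t + a_s S_t + δ_{s,t}` where `D_t` is a
common driver accumulating per-phase slopes, `S_t` a regime-shift signal
(0 → 1 across the shifted regime, decaying to ~0.3 as the shift partially
reverses) and `δ` i.i.d. N(0, 0.15²) species-year noise. Observation layer:
polygon depths follow a latitudinal gradient (80 m + 400 m · latitude
fraction + N(0, 50²), floored at 20 m) so depth and geography are partially
confounded, as on a real shelf; per tow, density is modulated by a Gaussian
depth niche `exp(−(depth−μ_s)²/2w_s²)`; presence is
Bernoulli(logistic(slope_s · ln density)); positive catches are lognormal
(σ = 0.8) around the density; from 1995 on, densities are multiplied by
`exp(k(L̄−L_s)/L̄)` clamped to [1, 10] (k = 1.2) — smaller fish caught more.
Tows per year are N(421, 62²) rounded and floored at 50, allocated
near-evenly across the 150 polygons with a fixed round-robin remainder — a
standing stratified design; a fully random allocation would inject
year-to-year common sampling variation that reads as spurious synchrony.
Tow positions are uniform within cells; tow depths add N(0, 8²) m.

The default collapse scenario covers 1981–2013 in five phases: stable
1981–86 (slope 0), synchronous decline 1987–94 (−0.35/yr, chosen so the
dominant species loses ~97% of biomass, the scale of a severe groundfish
collapse), shifted regime 1995–2004 (flat at the trough), compositional
recovery 2005–09 (+0.10/yr) and slow biomass growth 2010–13 (+0.12/yr).
Four large-bodied "commercial" species dominate initially; the shift signal
transfers dominance from species 1 to species 2, whose traits are set at the
pool medians/modes so that concentration on it depresses functional
dispersion during the shifted regime. Trait realism is not a goal — trait-
space geometry is; categorical levels are sampled from 3–5 level sets and
numeric traits are lognormal.

Ground truth contains the noiseless `log B`, the expected log catch (adding
the polygon-mean log depth kernel and the gear factor), the exact Bernoulli
presence rate at the realized tows, per-window synchrony of the noiseless
expectations, and a depth-structuring index (mean across species of the
variance of the log kernel over polygons).

**What passing tests show, and what they do not.** The generator reproduces
zero inflation, heavy tails, depth structure, a catchability break and
regime phases — so end-to-end tests demonstrate that the indicator suite
recovers *designed* dynamics from realistic sampling noise. It has no
species interactions, recruitment dynamics, spatial autocorrelation beyond
the depth gradient, or vessel effects; agreement on synthetic data is
therefore evidence about the estimators, not a validation of ecological
conclusions drawn from any real survey.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
scenario/analysis configuration; two runs with the same seed are
numerically identical. The validation suite runs the full default scenario
(33 years × ~421 tows × 30 species) end-to-end over 25 seeds with R = 199
synchrony randomizations, and uses smaller matrices (10 units, 5-year
windows, ≤ 1000-tow years) for the algorithmic oracles; the acceptance
script runs one full pipeline including the spatial stages (150 polygons,
~11 000 polygon pairs per year).

## Known limitations

* The screening ratio and recovery scaling are sensitive to the reference
  year and post-change window; both are configurable but default to the
  standard 1981 / 1995–2000 choices.
* The distance-decay regression treats polygon pairs as independent, so its
  R² values are descriptive rather than inferential.
* NMDS with few points and many ties can terminate at a local optimum; the
  multi-start default (20 + metric start) makes this rare but not
  impossible.
* The jackknife treats tows as independent; cluster sampling in a real
  survey would require leaving out tow clusters instead.
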