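# Methods

This note documents the scientific and numerical choices behind
`bbwosim`: what the model computes, why its parameters take the values
they do, what the synthetic landscape generator does and does not
emulate, and where the approach is limited.

## 1. State representation

The landscape is a regular grid of square cells, 250 m on a side
(6.25 ha), with row 0 at the northern edge.  Vegetation in a cell is a
list of cohorts (species × establishment time).  Internally the state is
a dense array `biomass[species, age_class, cell]` where age class *a*
corresponds to age *a* × timestep; a cohort exists wherever biomass is
positive.  This trades memory (a few hundred MB at most for the default
configurations) for fully vectorized dynamics: a 100×100-cell,
100-yr run takes a few seconds on one CPU.

Alongside the biomass array the state tracks, per cell: time since fire
(−1 = never burned in simulation), the stand age and conifer biomass
fraction *at the moment of the last burn* (`pre_fire_age`,
`pre_fire_conifer`), a landtype class, a fire region, a management area,
and land tenure (public/private).  The pre-fire records exist because
recently burned woodpecker habitat is defined by what burned — an old
conifer stand leaves high-quality snags, a young or deciduous stand does
not — while the post-fire cohort list only describes the regrowth.

Time bookkeeping: a step covering calendar years *t* → *t*+5 produces a
snapshot at *t*+5.  A cell burned during that step has time-since-fire 0
at that snapshot; the burned-habitat windows (1–5 and 6–10 yr post-fire)
therefore match the first and second *subsequent* snapshots, where
time-since-fire is 5 and 10.

## 2. Succession

Each 5-yr step:

* **Ageing** — every cohort moves up one age class.
* **Senescence** — a cohort of age *a* and species longevity *L* loses
  the biomass fraction `exp(m·(a − L)/L)` (shape `mortality_shape`
  *m* ≈ 15–25); the fraction reaches 1 at *a* = *L*, so no cohort
  outlives its species' longevity.  Residual biomass below 10⁻³ t/ha is
  cleaned up to keep the cohort set sparse.
* **Growth** — biomass increases by
  `timestep × maxANPP/1000 × g × (1 − B_cell/maxAGB)`, where `B_cell`
  is the cell's total biomass and `maxAGB` the *most generous* species
  limit present (a shared site carrying capacity).  The factor *g* is 1
  for species with a flat growth shape and `max(4p(1−p), 0.1)` with
  *p* = *a*/*L* for hump-shaped growers, peaking at mid-life.
* **Establishment** — a species can establish a new cohort (at age
  class 1, biomass 0.5 t/ha) in a cell if (i) site occupancy
  `B/maxAGB` is below its shade-tolerance threshold (0.25, 0.45, 0.65,
  0.85, 1.0 for tolerance 1–5), (ii) seed reaches the cell, and
  (iii) a Bernoulli draw with probability SEP succeeds.

**SEP** (species establishment probability per 5-yr timestep) derives
from a mean establishment time *t* (years) as `1 − (1 − 1/t)^5`: annual
establishment is a Bernoulli trial with probability 1/*t*, and SEP is
the probability of at least one success in five trials.

**Seed dispersal** uses an exponential kernel truncated at the species'
maximum dispersal distance, with the rate solved (Brent's method) so
that 95 % of dispersal falls within the effective dispersal distance.
Seed sources are cells holding a mature (age ≥ maturity) conspecific
cohort; distance to the nearest source is computed with a Euclidean
distance transform, so dispersal cost is independent of landscape size
per species.  Species with vegetative regeneration can also re-establish
locally from their own surviving cohorts.

## 3. Disturbances

**Fire.**  Each fire region has an annual burn rate *r* (expected
fraction of region area burned per year) and a mean fire size *S* (ha).
Per step, the number of fires is Poisson with mean
`timestep × r × region_area / S`; sizes are lognormal with mean *S* and
coefficient of variation 1 (σ² = ln(1 + CV²)), a standard heavy-tailed
fire-size model.  Each fire grows from a random ignition cell by
repeated accretion of random boundary neighbours (4-neighbour), which
produces contiguous, irregular burn shapes, and never crosses region
boundaries.  Burned cells lose all cohorts and record their pre-fire age
and composition.  Post-fire regeneration: serotinous species reseed in
the burn (age class 0) wherever they had a *mature* pre-fire cohort;
resprouters regrow from any pre-fire cohort.  The default calibration —
rate 1/150 yr⁻¹, mean size 500 ha — gives an expected 150-yr fire cycle;
the realized burned fraction per step is checked against `rate ×
timestep` by the test suite and the acceptance script.

**Spruce budworm.**  Outbreaks follow a deterministic schedule (first
onset at simulation year 35, 10-yr duration, 35-yr recurrence — two
outbreaks per century, matching the historical rhythm).  During an
outbreak, host cohorts lose biomass with probability-scaled severity:
host rank (balsam fir 1.0, white spruce 0.75, red spruce 0.5, black
spruce 0.25) × age-dependent mortality (0.25 / 0.55 / 0.85 for hosts
< 30, 30–60, > 60 yr).  Non-hosts are untouched.

**Harvest.**  Each management area has a constant-area target of
`annual_rate × area × timestep` per step (default 0.6 %/yr, inside the
0.4–0.8 %/yr range typical of boreal management plans).  Only cells
containing a cohort strictly older than 60 yr are eligible; cells are
drawn at random among eligible ones until the target or the eligible
pool is exhausted, and the shortfall is reported.  Public-tenure areas
are clearcut — only the youngest (≤ 5 yr) cohort survives, emulating
regeneration protection; private areas alternate between low (1–40 %)
and high (41–80 %) partial removal, drawn uniformly per cell.

**Climate.**  Scenarios `baseline`, `rcp26`, `rcp45`, `rcp85` carry a
forcing weight 0, 0.3, 0.6, 1.0.  The century is split into periods
2000–2010, 2011–2040, 2041–2070, 2071–2100 with phase 0, ⅓, ⅔, 1; a
step belongs to the period containing its end year.  Multiplicative
trends scale linearly with forcing × phase up to their 2100 endpoints
at full forcing: burn rate ×5 and mean fire size ×1.5 (fire-regime
driver); conifer SEP/maxANPP/maxAGB −40 % (black spruce −55 %),
deciduous +30 % (stand-scale driver).  SEP is clamped to [0, 1].  The
two drivers are toggled independently in experiments, and harvesting is
the third toggle.

## 4. Habitat classification and productivity

Six habitat types, with per-type mean home range (ha) and potential
productivity (fledglings per pair per year):

| type | definition | home range | productivity |
| --- | --- | --- | --- |
| old conifer, unburned | age > 80, conifer fraction ≥ 0.75 | 150 | 1.5 |
| old mixed, unburned | age > 80, 0.25 ≤ conifer < 0.75 | 300 | 1.0 |
| burned old conifer, 1–5 yr | pre-fire age > 80 and conifer ≥ 0.75 | 40 | 1.4 |
| burned young conifer, 1–5 yr | pre-fire age ≤ 80, conifer ≥ 0.75 | 100 | 0.25 |
| burned old conifer, 6–10 yr | pre-fire age > 80 and conifer ≥ 0.75 | 200 | 0.4 |
| non-habitat | everything else | — | 0 |

Burn windows take precedence: a cell with time-since-fire in 1–10 yr is
classified from its pre-fire records; burned mixed or deciduous stands,
and 6–10-yr burns of young stands, are non-habitat.  Cells burned more
than 10 years ago are classified like unburned cells from their current
stand.

Contiguous same-type cells are merged into patches (rook connectivity by
default, queen optional) with `scipy.ndimage.label`.  A patch whose area
is below its habitat's home range holds no breeding pair and contributes
nothing.  Two counting modes convert eligible patches into productivity:

* `"patches"` (default): one pair per eligible patch — the literal
  patch-count reading.
* `"home_ranges"`: `floor(area / home_range)` pairs per eligible patch.

The patch-count mode is scale-fragile on small grids: when old forest is
extensive it coalesces into one giant patch (count 1), and disturbance
can *increase* the count by fragmentation, making the response
non-monotone in habitat area.  The area-based mode is monotone and is
used for the directional experiments and the acceptance script; both
modes share the eligibility rule.  Totals are reported as densities per
100 km² (10⁴ ha).

## 5. Synthetic landscape generator

Real applications would initialize from forest inventory and satellite
maps.  The generator emulates the broad spatial structure such data
would provide:

* horizontal banding of fire regions and management areas (disturbance
  regimes vary along the south–north axis);
* a south–north gradient in the probability of conifer dominance
  (default 0.4 → 0.95), mirroring the hardwood-to-conifer transition;
* the southernmost management areas zoned private (default fraction
  0.127 of areas, minimum one band), the rest public;
* stand ages drawn from a truncated exponential (mean 150 yr), the
  stationary age distribution of a constant fire cycle, truncated at
  each species' longevity and floored to the 5-yr grid;
* dominant-cohort biomass at 75 % of an age-ramped maximum
  (`maxAGB × age/(age+40)`) with ±20 % noise; 40 % of cells carry a
  secondary cohort;
* random landtypes modulating `maxANPP`/`maxAGB` by ±15 %.

It does **not** emulate: realistic spatial autocorrelation of
composition and age (cells are independent given the gradient), roads
and hydrography, inventory-based species mixtures (an 8-species pool
with fixed weights stands in for mapped abundances), topography, or any
calibration to a particular region's fire history.  Because ages are
sampled independently and truncated at longevity, a sizeable mass of
cells starts at or near the senescence cliff, producing a pulse of
old-forest mortality in the first simulated decade — visible as a sharp
initial drop in old-forest habitat in the worked examples.

## 6. Experiments and statistics

The experiment harness runs the full 2×2×2 factorial
(harvest × fire-regime response × stand-scale response), per climate
scenario, with paired seeds: every toggle combination of a replicate
shares the same initial landscape and the same master seed.  The master
seed is split into named independent streams ("fire", "harvest",
"establishment", "sbw") via `numpy`'s `SeedSequence.spawn`, so toggling
one process does not perturb the random draws of the others — the
pairing isolates each driver's effect.

Driver importance is computed two ways:

* **ω²** from a balanced three-way, mean-based type-I ANOVA (own
  implementation, cross-checked against `statsmodels` OLS ANOVA to
  10⁻¹⁰ in the tests): `ω² = (SS_eff − df_eff·MS_err)/(MS_err +
  SS_tot)`.  Values are reported as computed (slightly negative for null
  effects, not clamped); an all-constant response raises a degeneracy
  error rather than returning 0/0.
* **ΔProd / ΔB**: the percentage difference in mean productivity (or
  one species' mean AGB) between the full model and the reduced model
  omitting one driver, `100 × (full − reduced)/reduced`, with a zero
  reduced-model mean flagged as undefined (NaN) instead of raising.

## 7. Numerical and I/O choices

* Biomass below 10⁻³ t/ha is zeroed after each step (denormal-cohort
  cleanup); establishment writes 0.5 t/ha.
* The dispersal-kernel rate is found with `scipy.optimize.brentq` to
  machine precision; distances to seed sources use
  `scipy.ndimage.distance_transform_edt`.
* Rasters are ESRI ASCII grids — plain text, dependency-free, readable
  by every GIS — with floats printed at 17 significant digits so
  write/read round-trips are bit-exact; cohort tables are CSV re-read
  with round-trip float parsing for the same guarantee.
* A run manifest (YAML) stores the SHA-256 of the canonicalized
  configuration plus seed, scenario and toggles; together with the
  package version this reproduces any run exactly.
* All randomness in the CLI and the acceptance script derives from a
  single `--seed`; derived seeds stay below 2³¹.

## 8. Limitations

* Desk-scale grids (10³–10⁴ cells against the ~10⁷ of a regional
  study) cannot reproduce landscape-level magnitudes; results here are
  directional and property-level, not calibrated predictions.  The
  acceptance script's century-long declines (≈ 98–100 % across
  scenarios on the default landscape) reflect this scale and the
  generator's initial age structure, and should not be read as regional
  projections.
* The initial-age senescence pulse (§5) depresses early habitat; a
  spin-up period or an inventory-based age map would remove it.
* Fire shapes are simple stochastic accretion patterns; no weather,
  fuel or suppression sub-models.
* The budworm schedule is deterministic and its mortality parameters
  coarse.
* Harvesting selects cells at random within a management area (optional
  clustering is rudimentary); no road network, block adjacency or
  volume targets.
* Habitat quality is a static per-type coefficient; no response to
  snag density, beetle dynamics, or within-type variation.
* Private/public tenure is banded by whole management areas, so the
  realized private fraction is coarser than the configured one on small
  grids.
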