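# Fully commented bbwosim configuration.
#
# Every key is optional: an empty file (or any omitted key) falls back to
# the built-in default, which is the value shown here unless noted.
# Unknown keys are rejected with an error, so typos fail loudly.
# Species entries are merged over the built-in trait table, so you only
# need to list the traits you want to change.

grid:
  n_rows: 100          # grid height (cells); row 0 is the northern edge
  n_cols: 100          # grid width (cells)
  cell_area: 6.25      # hectares per cell (250 m x 250 m)
  origin_year: 2000    # calendar year of the initial snapshot
  timestep: 5          # years per simulation step
  horizon: 100         # simulated years; must be a multiple of timestep

# Synthetic landscape generator (initial conditions only).
synthetic:
  n_fire_regions: 3        # horizontal bands, each with its own fire regime
  n_management_areas: 5    # horizontal bands with independent harvest targets
  private_fraction: 0.127  # fraction of management areas zoned private
                           # (southernmost bands; private land gets partial
                           # cutting, public land gets clearcuts)
  conifer_gradient: [0.4, 0.95]  # probability a cell is conifer-dominated at
                                 # the southern and northern edge; interpolated
                                 # linearly in between
  age_distribution_mean: 150.0   # mean of the truncated-exponential initial
                                 # stand-age distribution (years)
  n_landtypes: 5           # number of soil/climate classes, assigned randomly
  initial_stocking: 0.75   # initial biomass as a fraction of the asymptotic
                           # age-dependent maximum
  rng_seed: 0              # generator seed (overridden by CLI --seed)
  species_pool:            # relative weight of each species as the dominant
    PICE.MAR: 0.35         # black spruce
    ABIE.BAL: 0.20         # balsam fir
    PINU.BAN: 0.10         # jack pine
    PICE.GLA: 0.05         # white spruce
    LARI.LAR: 0.03         # tamarack
    POPU.TRE: 0.12         # trembling aspen
    BETU.PAP: 0.10         # paper birch
    ACER.RUB: 0.05         # red maple

# Stochastic fire regime (baseline calibration; climate scaling below).
fire:
  annual_burn_rate: 0.006666666666666667  # expected fraction of each region
                                          # burned per year (1/150-yr cycle)
  region_burn_rates: null   # optional map {region index: rate} overriding
                            # annual_burn_rate per fire region
  mean_fire_size: 500.0     # mean of the lognormal fire-size distribution (ha)
  size_cv: 1.0              # coefficient of variation of fire sizes
  rate_multiplier_max: 5.0  # burn-rate multiplier reached by 2100 at full
                            # climate forcing (RCP 8.5)
  size_multiplier_max: 1.5  # mean-fire-size multiplier reached by 2100
  spread_prob: 1.0          # per-neighbour accretion probability during
                            # fire-shape growth

# Spruce budworm outbreaks (deterministic schedule, stochastic mortality).
sbw:
  recurrence: 35        # years between outbreak onsets
  max_duration: 10      # outbreak length (years)
  phase: 35             # simulation year of the first onset
  host_ranking: [ABIE.BAL, PICE.GLA, PICE.RUB, PICE.MAR]  # preferred first
  rank_severity: [1.0, 0.75, 0.5, 0.25]  # mortality scaling per host rank
  age_mortality: [0.25, 0.55, 0.85]      # base mortality for hosts aged
                                         # <30 / 30-60 / >60 years

# Timber harvesting (constant-area prescriptions per management area).
harvest:
  annual_rate: 0.006    # fraction of each management area cut per year
  eligibility_age: 60   # only cells with a cohort strictly older are cut
  partial_low: [0.01, 0.40]   # removal fraction range, low-level partial cut
  partial_high: [0.41, 0.80]  # removal fraction range, high-level partial cut
  patch_clustered: false      # draw cut cells independently (false) or
                              # seeded in clusters (true)

# Woodpecker habitat classification and productivity scoring.
habitat:
  conif_threshold: 0.75  # conifer biomass fraction for "coniferous" stands
  mixed_lower: 0.25      # lower bound of the "mixed" composition class
  connectivity: 4        # patch connectivity: 4 (rook) or 8 (queen)
  count_mode: patches    # "patches": one breeding pair per eligible patch;
                         # "home_ranges": floor(area / home range) pairs per
                         # eligible patch (recommended on small grids)
  coefficients:          # per habitat type: mean home range (ha) and
                         # potential productivity (fledglings / pair / yr)
    OLD_CONIF_UNBURNED: {home_range: 150.0, productivity: 1.5}
    OLD_MIXED_UNBURNED: {home_range: 300.0, productivity: 1.0}
    BURNED_OLD_CONIF_1_5: {home_range: 40.0, productivity: 1.4}
    BURNED_YOUNG_CONIF_1_5: {home_range: 100.0, productivity: 0.25}
    BURNED_OLD_CONIF_6_10: {home_range: 200.0, productivity: 0.4}

# Cohort succession numerics.
succession:
  light_thresholds: [0.25, 0.45, 0.65, 0.85, 1.0]  # max site occupancy at
                          # which a species of shade tolerance 1..5 can
                          # still establish
  regen_biomass: 0.5      # biomass of a newly established cohort (t/ha)

# Climate-change scaling applied to stand-scale parameters (SEP, maxANPP,
# maxAGB) by 2100 at full forcing; intermediate pathways and periods are
# interpolated.
climate:
  conifer_decline: 0.4            # fractional loss for conifers
  black_spruce_extra_decline: 0.15  # additional loss for black spruce
  deciduous_gain: 0.3             # fractional gain for deciduous species
  sep_follows_growth: true        # apply the same trend to SEP

# Species trait overrides, merged over the built-in 17-species table.
# Shown: making jack pine slightly longer-lived and raising its
# establishment probability.  Any subset of traits may be given; the full
# set is: longevity, maturity_age, shade_tolerance, effective_dispersal,
# maximum_dispersal, vegetative_regen, post_fire_regen (none | serotiny |
# resprout), growth_shape, mortality_shape, is_conifer, sep_baseline.
species:
  PINU.BAN:
    longevity: 160
    sep_baseline: 0.80
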