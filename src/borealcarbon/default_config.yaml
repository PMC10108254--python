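# Default configuration for borealcarbon.
#
# Literature-derived coefficient tables (allometry, dead-wood density ratios,
# carbon fractions, decomposition rate constants) are EDITABLE PLACEHOLDERS of
# realistic magnitude, shipped in the style of the published Fennoscandian
# sources (Marklund 1988 biomass functions; Sandström et al. 2007 dead-wood
# densities; Shorohova & Kapitsa 2014 / Yatskov et al. 2003 decay constants).
# For analyses of real field data, replace them with the published values for
# your species and region.  All other entries are method parameters with
# defaults matching a northern-Sweden chamber/inventory campaign.

site:
  plot_radius_m: 10.0              # permanent inventory plot radius
  min_inventory_dbh_cm: 3.0        # trees below this DBH are not inventoried
  age_class_bounds:                # [min_age, max_age] per class, years
    initiation: [5, 27]
    young: [31, 58]
    middle_aged: [61, 78]
    mature: [80, 105]
    old: [131, 211]

carbon:
  live_c_fraction: 0.50            # C per unit dry mass, living biomass
  dead_c_fraction:                 # per decay class (1 = fresh, 5 = rotten)
    1: 0.50
    2: 0.50
    3: 0.49
    4: 0.48
    5: 0.47

# ln(B_kg) = a + b * d/(d + c), d = DBH in cm, per species and component.
allometry:
  pine:
    stem:         {a: -2.34, b: 11.33, c: 13.0}
    branches:     {a: -2.91, b:  7.50, c: 10.0}
    foliage:      {a: -3.77, b:  7.10, c:  7.0}
    coarse_roots: {a: -3.40, b:  8.60, c: 12.0}
  spruce:
    stem:         {a: -2.20, b: 11.00, c: 14.0}
    branches:     {a: -1.90, b:  7.40, c: 12.0}
    foliage:      {a: -2.60, b:  7.80, c: 10.0}
    coarse_roots: {a: -3.10, b:  8.50, c: 13.0}
  birch:
    stem:         {a: -2.60, b: 11.20, c: 12.0}
    branches:     {a: -3.20, b:  8.00, c: 11.0}
    foliage:      {a: -4.30, b:  6.90, c:  8.0}
    coarse_roots: {a: -3.60, b:  8.70, c: 12.0}
  other_deciduous:
    stem:         {a: -2.70, b: 11.10, c: 12.0}
    branches:     {a: -3.30, b:  7.90, c: 11.0}
    foliage:      {a: -4.40, b:  6.80, c:  8.0}
    coarse_roots: {a: -3.70, b:  8.60, c: 12.0}

# Dead-tree structural density relative to live wood, per decay class.
dead_density_ratio:
  1: 0.97
  2: 0.85
  3: 0.65
  4: 0.45
  5: 0.30

litterfall:
  trap_area_m2: 0.25               # circular funnel trap collecting area
  n_traps: 3

understory:
  quadrat_area_m2: 0.25            # destructive clip quadrat
  n_quadrats: 3

ingrowth:
  core_diameter_cm: 10.0
  core_depth_cm: 30.0
  installation_span_yr: 1.25       # June yr0 to autumn yr1

chamber:
  base_side_m: 0.45                # square chamber footprint
  height_m: 0.20
  deadband_s: 10.0                 # discarded after closure
  min_points: 5
  pressure_kpa: 101.325
  negative_flux_tolerance: 0.05    # umol m-2 s-1; more negative -> warning

lloyd_taylor:
  t_ref_k: 283.15                  # reference temperature (10 degC)
  t0_k: 227.13                     # Lloyd & Taylor (1994) zero-activity T
  e0_grid: [0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 500.0]

annual_sums:
  step_s: 1800                     # half-hourly soil-temperature records
  max_gap_fraction: 0.05           # tolerated missing fraction, interpolated

# Dead-wood decomposition rate constants k (yr^-1) per species, position and
# decay class; annual respired fraction is 1 - exp(-k) by default.
decay_constants:
  pine:
    standing: {1: 0.010, 2: 0.020, 3: 0.030, 4: 0.040, 5: 0.050}
    downed:   {1: 0.020, 2: 0.035, 3: 0.050, 4: 0.065, 5: 0.080}
  spruce:
    standing: {1: 0.012, 2: 0.022, 3: 0.033, 4: 0.045, 5: 0.055}
    downed:   {1: 0.022, 2: 0.038, 3: 0.055, 4: 0.070, 5: 0.085}
  birch:
    standing: {1: 0.015, 2: 0.030, 3: 0.045, 4: 0.060, 5: 0.075}
    downed:   {1: 0.030, 2: 0.050, 3: 0.070, 4: 0.090, 5: 0.110}
  other_deciduous:
    standing: {1: 0.015, 2: 0.030, 3: 0.045, 4: 0.060, 5: 0.075}
    downed:   {1: 0.030, 2: 0.050, 3: 0.070, 4: 0.090, 5: 0.110}
rhdw_mode: exponential             # 'exponential': pool*(1-e^-k); 'linear': pool*k

production:
  mortality_increment_counted: true   # count growth of trees dying in the interval
  shrink_tolerance_cm: 0.1            # DBH shrink beyond this -> clamp + warning

trends:
  rh_form: poly2_age               # 'poly2_age' (quadratic in age) or 'poly2_logage'
  include_thinned: true
  min_trend_age: 1.0

rotation:
  horizon_yr: 220.0
  step_yr: 0.1
  lcsr_mode: half                  # 'half': C(a*)/2; 'sawtooth': exact time-average

drivers:
  n_components: 2
  varimax_tol: 1.0e-8
  varimax_max_iter: 500

# ---------------------------------------------------------------------------
# Synthetic landscape: the study design being emulated (stand counts, age
# structure, species and soil mix) and the true flux-age curves with
# measurement-noise settings.  Curve defaults are calibrated so that class
# means fall at field-realistic magnitudes (peak NPP ~ 390, peak NEP ~ 175,
# RH ~ 210-230 g C m-2 yr-1).
synthetic:
  class_counts: {initiation: 8, young: 9, middle_aged: 13, mature: 14, old: 6}
  n_pine: 28
  n_spruce: 22
  n_till: 35
  n_sediment: 15
  n_clearcuts: 3                   # youngest stands, ages 5-7, no trees >= 3 cm
  include_thinned_stand: true      # one 26-yr stand thinned in the last year
  include_source_clearcut: true    # one clear-cut forced to net C emission
  n_additional_old: 0              # extra old stands with BA-imputed budgets
  years: [2015, 2016, 2017, 2018]  # inventory years; budgets for 2016-2018
  true_curves:                     # exp(b0 + b1 ln a + b2 ln^2 a), g C m-2 yr-1
    npp_t: {b0: 0.342, b1: 2.5438, b2: -0.294}
    anpp_u: {b0: 5.571, b1: -0.539, b2: 0.0}
    rh_s_poly: {c0: 230.9, c1: -0.6205, c2: 0.00308}   # quadratic in age
    rh_dw: {b0: -1.5, b1: 0.8, b2: -0.06}
  structure:
    max_quadratic_mean_dbh_cm: 30.0   # D(a) = max * a/(a+40)
    dbh_age_halfsat_yr: 40.0
    max_basal_area_m2_ha: 34.0        # BA(a) = max * a/(a+30)
    ba_age_halfsat_yr: 30.0
    dbh_lognormal_sigma: 0.25
    mortality_rate_yr: 0.008
  partition:
    litter_fraction_of_npp_t: 0.20    # L(a) = fraction * NPP_t curve
    growth_fraction_of_npp_t: 0.55    # target (dB_live + mortality) share
    min_bnpp_t_fr: 5.0                # g C m-2 yr-1 floor
    root_to_shoot_understory: 0.80    # true r_u = BNPP_u / ANPP_u
  heterogeneity:                   # between-stand site-quality scatter
    npp_sd: 0.12                   # lognormal SD on tree production level
    understory_sd: 0.15            # lognormal SD on understory production
    rhs_sd: 0.05                   # lognormal SD on annual RH_s level
  soil_temperature:
    annual_mean_c: 2.4
    annual_amplitude_c: 9.0
    peak_doy: 205
    stand_mean_sd_c: 0.5
    noise_sd_c: 0.3
  lloyd_taylor_truth:
    e0_mean: 308.56
    e0_sd: 30.0
    source_clearcut_rhs_factor: 1.35
  campaigns:
    n_per_year: 8
    first_doy: 130                   # early May
    last_doy: 295                    # late October
    co2_start_ppm: 420.0
    sample_interval_s: 15.0
    n_samples: 13
  noise:                             # multiplicative SDs; 0 disables
    chamber_flux: 0.10
    litter_trap: 0.08
    clip_mass: 0.10
    ingrowth_mass: 0.15
    deadwood_pool: 0.10
    drivers: 0.08
  drivers_truth:
    lai_lmax: 4.5                    # saturating LAI-biomass curve
    lai_halfsat_mg_ha: 60.0
    n_lai_measured: 25
    cn_base: 28.0
    cn_nep_slope: -0.02
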