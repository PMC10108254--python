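# Methods

This note documents the models implemented in `borealcarbon`, the choices
made where the underlying field methodology leaves the design open, and
what the synthetic landscape does and does not demonstrate.

## Budget accounting

Each stand-year budget is assembled from eight measured components
(ANPP_t, L, BNPP_t-cr, BNPP_t-fr, ANPP_u, BNPP_u, RH_s, RH_dw); all
derived sums (NPP_t, NPP_u, BNPP_fr, NPP, RH, NEP) are computed at
composition time, so the five budget identities hold exactly by
construction and are re-verified on every write.  NPP and RH components
are constrained non-negative; NEP may take either sign (positive = net
ecosystem C uptake).  All statistics (class means, trend fits, PCA,
correlations) operate on multi-year stand means, not individual years.

### Tree production

Biomass follows the ln-linear allometric family
`ln B = a + b·d/(d+c)` (B in kg dry mass, d = DBH in cm) per species and
component (stem, branches, foliage, coarse roots).  Height terms are
omitted: the packaged coefficients are editable placeholders of realistic
magnitude standing in for published Fennoscandian tables, and any
DBH-driven table can be substituted through the YAML configuration.
Carbon is 50% of dry mass for living tissue; dead trees take a
decay-class-specific structural density ratio and C fraction.

Production accounting over an inventory interval:

- surviving trees contribute their allometric biomass increment;
- trees that die contribute their increment too (the live pool loses
  their start-of-interval mass, the mortality transfer adds their
  death-year mass — the net is the growth that actually happened), and
  their stock enters the dead-wood pool;
- harvested trees (status `removed`) are dropped from both ends of the
  interval, so thinning is not negative production;
- trees first seen in an inventory (ingrowth past the 3-cm threshold)
  contribute their full biomass.

Negative live-pool changes that survive this treatment are passed through
with a logged warning rather than clamped; the final budget composition
clamps (with a warning) only small negative totals.  Litterfall is the
trap total divided by total trap area times the C fraction
(3 × 0.25 m² funnel traps per plot by default).  Apparent DBH shrinkage
beyond 0.1 cm is treated as measurement error and clamped to zero
increment.  Ring-width series (2× ring width = diameter increment) can
back-cast increments for years without repeated inventories.

Recent clear-cuts carry no inventory-sized trees; their tree biomass and
litterfall are imputed from ordinary least-squares lines of those
quantities against age over the remaining initiation-class stands
(predictions clamped at zero), the biomass slope serving as the annual
increment.

### Understory and fine roots

Understory ANPP from seasonal clip harvests: herb production equals peak
(August) herb biomass; shrub, moss and lichen production is the
June→August pool increase, floored at zero per functional type (a
biomass-difference estimate cannot attribute negative production).  The
single clip year is scaled to the other study years by the dwarf-shrub
shoot-increment index, all functional types sharing the shrub factor.

Fine-root production (trees + understory) comes from ingrowth cores:
per-core mass / core surface area / installation span (default 1.25 yr
for a June-to-second-autumn deployment — the exact annualisation is a
package choice, configurable), averaged over cores, times the C fraction.
The single ingrowth year is extended to all years through the ratio of
fine-root production to total ANPP in that year.  Partitioning uses the
understory root-to-shoot ratio r_u estimated in the clear-cuts, where
tree fine roots a few years after harvest are assumed negligible and all
ingrowth is understory.  Elsewhere `BNPP_u = min(r_u·ANPP_u, BNPP_fr)` —
capped so the understory share can never exceed the measured total — and
`BNPP_t-fr = BNPP_fr − BNPP_u`, conserving mass exactly.

### Heterotrophic respiration

Chamber flux is the ordinary-least-squares slope of the headspace CO₂
series after a 10-s deadband (≥5 usable points), converted with the
ideal-gas molar density: `flux = slope · (V/A) · P/(R·T_air)`.  The
steady-state chamber is taken at face value (no saturation correction);
negative fluxes are clamped to zero with a warning beyond a small
tolerance.

Each plot gets a two-parameter Lloyd–Taylor temperature response
`R(T) = R_ref·exp(E0·(1/(T_ref−T0) − 1/(T−T0)))` with T_ref = 283.15 K
and T0 = 227.13 K fixed (the 1994 convention; two free parameters is what
~24 campaign points support stably).  Fitting minimises squared error on
the natural flux scale; a deterministic coarse grid over E0 (closed-form
conditional R_ref at each node) supplies the start for least-squares
refinement, and non-convergence falls back to the constant (E0 = 0) model
with a warning.  Plot-specific fits pool all study-year campaigns
(8 per year over 3 years by default).  Annual RH_s integrates the fitted
response over the plot's half-hourly soil-temperature record
(gaps ≤5% linearly interpolated; more is an error), full calendar year —
the winter share is extrapolated by the same response, a recognised
approximation.

Dead-wood respiration applies species-, position- and decay-class-
specific rate constants k to the dead-wood C pools with an exact
single-exponential year step, `pool·(1−e^(−k))` (a `linear` mode gives
plain `pool·k`; the difference is ≤2% for small k).  All decomposed mass
is treated as respired — no fragmentation or leaching split.

### Budgets for additional old stands

Old stands beyond the main design carry only inventory/coring
measurements.  Their remaining production components come from fixed mean
ratios to tree ANPP over the main stands (litterfall relative to the
growth part, since these stands have no traps), and RH_s / RH_dw from
linear-in-basal-area regressions (≥5 reference stands; extrapolation
outside the reference BA range warns).  These stands enter the old-class
summary but never the trend fits.

## Trend curves and rotation calculus

Production fluxes are fitted with
`F(age) = exp(b0 + b1·ln age + b2·ln² age)` by Levenberg–Marquardt on the
natural flux scale (the closed-form log-space linear solve provides the
deterministic start and the fallback).  Fitting in natural scale weights
the large fluxes where the C accounting happens; b2 < 0 gives the hump
with interior maximum at `exp(−b1/2b2)`.  RH and RH_s, which show no
exponential age pattern, use an ordinary quadratic in age (quadratic in
ln age available as a config switch).  The thinned stand stays in the
fits by default (a flag excludes it).  NEP(age) is never fitted directly:
it is the lazy difference of the NPP and RH curves, with ages below 1
clamped to NEP(1) since the log-age form is undefined at 0.

Rotation calculus on NEP(age): cumulative NEP is a trapezoidal integral
from age 0 (the sub-year clamp makes the integrand defined everywhere;
the analytic test curves integrate exactly).  The optimum rotation age is
the first crossing, beyond the NEP peak, of current NEP below the
cumulative mean C(a)/a, located by bisection to 0.01 yr — by the
mean-annual-increment culmination identity this equals the argmax of
C(a)/a.  A curve with no interior crossing returns the horizon with a
flag.  The carbon compensation point is the first return of the
cumulative balance to zero after an initial net loss (linear
interpolation between grid points; 0 if never negative).  LCSR defaults
to `C(a*)/2` — the time-average of an idealised linear sawtooth over
repeated rotations; the exact time-average `(1/a*)∫C` is available as
`lcsr_mode: sawtooth` and differs for non-linear trajectories.  The
steady-state harvest rate is reported as 100/a* % yr⁻¹.  Defaults:
horizon 220 yr, step 0.1 yr (halving the step moves the cumulative by
<0.1%).

## Driver analysis

PCA runs on the correlation matrix (drivers carry heterogeneous units),
loadings are eigenvectors scaled by √eigenvalue, varimax-rotated with
Kaiser normalisation (tolerance 1e-8, ≤500 sweeps), sign convention:
largest-magnitude loading per component positive.  Two components are
retained by default.  The primary analysis includes the budget fluxes and
NEP as active variables alongside the eight abiotic/biotic drivers; the
secondary analysis pairs tree NPP with the drivers alone.  Pearson
correlations of NEP and NPP_t with each driver are reported overall and
within age classes; groups with n < 3 or zero variance are marked
not-computed rather than guessed.  Stands without direct LAI measurements
are filled from a saturating Michaelis–Menten-type LAI–biomass fit over
the measured subset (the true relationship is site-specific and
config-overridable).

## The synthetic landscape

The generator emulates a 50-stand campaign across five age classes
(8/9/13/14/6 stands at ages 5–27, 31–58, 61–78, 80–105, 131–211 yr),
28 pine / 22 spruce stands on 35 till / 15 sediment soils, three recent
clear-cuts (ages 5–7, no inventory trees), one thinned 26-yr stand
(25% of trees `removed` in the final year) and one clear-cut forced to
net C emission (its RH_s scaled ×1.35).  Four annual inventories
(2015–2018) give three budget years.

Truth is built forward from smooth flux–age curves — tree NPP
log-quadratic with a peak near 76 yr, declining understory production,
a shallow U-shaped RH_s in age, small increasing RH_dw — calibrated so
class means land at field-realistic magnitudes (peak NPP ≈ 390, peak
NEP ≈ 175, RH ≈ 200–230 g C m⁻² yr⁻¹), with lognormal between-stand
site-quality scatter (SD 0.12 on tree production, 0.15 on understory,
0.05 on RH_s).  Individual trees are simulated so that allometric
bookkeeping reproduces the stand production targets: tree counts come
from a basal-area–age curve, DBH from a lognormal around a quadratic-
mean-DBH–age curve, and the common diameter increment is solved each year
from the stand's target growth via the allometric derivative.  Every
measurement is emitted so that noise-free processing recovers the truth:
trap masses invert the litterfall formula, clip masses the seasonal-
difference formula, core masses the ingrowth formula, and chamber CO₂
series are straight lines whose post-deadband slope returns exactly the
Lloyd–Taylor flux at the campaign soil temperature.  Soil temperature is
a half-hourly sinusoid (annual mean 2.4 °C, amplitude 9 °C, peak day
205) with stand offsets and white noise.  Measurement noise is
multiplicative Gaussian per observation (defaults: 10% chamber flux, 8%
litter trap, 10% clip, 15% ingrowth core, 10% dead-wood pool, 8%
drivers); a seed fully determines the bundle.

What passing tests show — and don't.  Noise-free recovery at machine
precision demonstrates that the processing chain inverts the generating
equations consistently, including the clear-cut ratio logic and the
mortality/removal conventions; it cannot validate the allometric,
decay-constant or temperature-response *values* against real forests,
which enter both generator and pipeline from the same configuration.
For the three clear-cuts the generator defines truth through the same
age-relationship helper the pipeline uses, so their recovery checks
consistency rather than an independent derivation.  Real campaigns
additionally feature non-Gaussian and correlated errors, chamber
artefacts, missing data, species mixtures and disturbance histories the
generator does not emulate.

## Problem sizes and numerical tolerances

The default test and acceptance runs use the full 50-stand design (three
budget years, ~5,000 tree records, 1,200 chamber campaigns, 3-year
half-hourly temperature series per stand); the pipeline completes it in
seconds, and reduced 16–19-stand configurations are used where many
repeat runs are needed.  Key tolerances: budget identities re-verified at
1e-9 relative; CSV round-trips exact to 1e-9; Lloyd–Taylor refinement and
trend fits run to ~1e-12 optimizer tolerances; rotation bisection to
0.01 yr.  Degenerate inputs have defined behaviour throughout:
temperature-insensitive chamber data collapses to the constant-response
model, constant flux-age data to a flat curve, curves without an interior
optimum or a compensation point return the horizon with an explicit flag,
and n = 1 age classes report an undefined confidence interval.

## Known limitations

- No height/taper terms in the allometry; bark and foliage turnover are
  not modelled separately from litterfall.
- No soil-moisture term in the respiration model (temperature was the
  stronger predictor at the plot scale); no trenching-artefact
  correction; winter RH_s is an extrapolation of the snow-free response.
- The understory root-to-shoot ratio is assumed constant across the
  landscape and the ingrowth-to-ANPP ratio constant across years.
- Three-year budgets are treated as independent annual realisations; no
  autocorrelation structure, and no bootstrap uncertainty on the trend
  curves or rotation quantities.
- Rotation calculus ignores harvest-product pools, substitution effects,
  discounting and non-CO₂ forcing: it is a stand-level C balance only.
- The printed steady-state harvest rate is 100/a*; other definitions of a
  landscape harvest rate exist and can give slightly different numbers.
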