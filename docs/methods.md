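# Methods

This note documents the statistical models, the synthetic observation
generator, and the numerical and design choices behind `arcticseb`.

## Harmonization of sub-daily records

Sub-daily records arrive in long format (site, timestamp in local standard
time, variable, value, QC flag, network, replicate). Processing order:

1. **QC filter.** Gap-filled-flagged values are dropped (only direct
   measurements enter the analysis). Plausibility bounds: shortwave and
   longwave radiation ≤ 1400 W m⁻²; incoming/outgoing radiation components
   ≥ 0 (turbulent fluxes may legitimately be negative and are not clipped);
   albedo within [0, 1]; air and surface temperature ≥ −100 °C. Removals
   are counted per rule; the filter is idempotent.
2. **Sign convention.** H, LE and G are harmonized to positive-away-from-
   surface; input declared in the opposite convention is flipped exactly
   once (a second flip restores the input).
3. **Daily admission.** A stream-day (site × network × replicate × variable
   × civil day) qualifies when at least 65 % of the nominal slots
   (1440/timestep) are present **and** the longest run of consecutive
   missing slots is at most 4.8 h. Both thresholds are inclusive. The
   completeness denominator is the nominal slot count of the full 24 h day,
   and the day boundary closes gap runs (a day starting 6 h late carries a
   6 h gap). Qualifying days get mean/min/max.
4. **Merging.** Daily values are averaged across replicate sensors within a
   network first, then across networks reporting the same site, so
   unbalanced replication within one network cannot skew the cross-network
   mean.
5. **Derived radiation.** `SW_net = SW_in − SW_out`, `LW_net = LW_in −
   LW_out`, `R_net = SW_net + LW_net`, filled only where not directly
   measured. Daily albedo is the ratio of daily mean outgoing to incoming
   shortwave (energy-weighted, not the mean of instantaneous ratios) and is
   undefined when daily mean `SW_in` < 10 W m⁻², avoiding low-sun
   blow-ups. Surface temperature is taken as observed; inverting it from
   `LW_out` is deliberately not done by default.

On noise-free synthetic data the radiative identity
`R_net = SW_in(1 − albedo) + LW_in − εσT_surf⁴` holds to machine precision
with ε = 1, because the generator emits `LW_out` as the Stefan–Boltzmann
emission of its simulated surface temperature.

## Potential shortwave radiation and normalization

"Maximum potential incoming shortwave" is top-of-atmosphere irradiance on a
horizontal surface at the day's minimum solar zenith: `S0·E0(d)·cos(φ − δ)`
with S0 = 1361 W m⁻², Spencer's series for declination δ and eccentricity
factor E0, and zero when the sun stays below the horizon. No atmospheric
transmissivity, terrain or horizon model is applied: the normalization only
needs a consistent astronomical scale, and site slopes at the relevant
stations are gentle at the 500 m averaging scale. Normalized fluxes are
`n.X = 100·X / s_pot_max` per day (normalization before seasonal
averaging), undefined when `s_pot_max` < 1 W m⁻² (polar night guard).

## SEB-drivers

Ten numeric and five categorical drivers per site. Four numeric drivers are
computed from input series, the rest are site metadata (in a real
application they come from gridded products; raster extraction is out of
scope here):

* **Conrad continentality** `1.7·(T_max − T_min)/sin(φ + 10°) − 14` from
  the warmest- and coldest-month mean temperatures. The sine is evaluated
  with the offset in **degrees** (Conrad's classical form); an offset of
  +10 added to a latitude in radians is dimensionally implausible, but the
  variant is switchable (`angle_unit="radians"`) for comparison with texts
  that print it that way. Multi-year input yields the mean of yearly
  indices.
* **Summer warmth index**: annual sum of monthly mean temperatures above
  0 °C (°C·months), averaged across years.
* **Snow amount** (SWE proxy): annual sum of precipitation on days with
  mean air temperature ≤ 0 °C (the 0 °C bound is inclusive).
* **Snow duration**: per site-year, the spring snow-free date is the mean
  DOY of the last spring "snow" day and the first following "no snow" day,
  the autumn snow-onset date the mean DOY of the last autumn "no snow" day
  and the first "snow" day; duration is their difference, and the driver is
  the per-site median across years. Transient events are handled by
  restricting the spring search to DOY 1–212 and the autumn search to DOY
  182–366 and taking the **last** spring and **first** autumn transition;
  a year whose transitions come out inverted (an event in the window
  overlap) is flagged missing rather than given a negative duration.

## Variance partitioning

Responses are seasonal site means: a site-year enters when ≥ 80 % of the
season's days carry a value; the site value is the across-year mean. For
each unordered pair (A, B) of drivers and each response, three OLS models
(A), (B), (A, B) give plain R²; then

* `first(A) = 100·R²(A)`,
* `last(A) = 100·[R²(A,B) − R²(B)]`,
* `average(A) = (first + last)/2`,

and symmetrically for B. For two predictors the order-average equals the
LMG (average-over-orderings) decomposition. Per driver and response the
summary reports mean/min/max of the average share across the driver's 14
pairs.

Choices: plain (not adjusted) R², matching "% explained variance" and
avoiding negative values by construction; negative *last* shares (possible
under suppression/collinearity) are kept raw internally — so the identity
`first(A) + last(B) = 100·R²(A,B)` is exact — and floored at 0 only in the
reported summary. Categorical drivers enter as full dummy blocks and their
share is the block's joint contribution. Sites with a missing driver value
are dropped listwise per pair, not globally. Models with fewer than
(coefficients + 3) observations or singular designs are skipped and
counted. Bookkeeping distinguishes enumerated ordered models
(pairs × 2 × responses; 2940 for 15 drivers and 14 responses) from models
actually evaluated.

**Identifiability of recovery experiments.** With plain R² a k-level
categorical driver picks up a spurious share of roughly (k−1)/n of the
residual variance in any single 2-predictor model. In a 15-driver table the
residual of a pair model contains the 13 absent drivers, so at small n
(tens of sites) chance correlations can outrank a genuinely dominant
driver. The dominant-driver recovery experiment therefore uses 40 sites per
vegetation class (n = 200) by default; at that size a driver generating 4×
the variance of every other driver is top-ranked in ≈ 98 % of replicates.
This is a property of the method's sample-size requirements, and it is why
per-driver rankings from networks of ~30 sites should be read jointly with
the reported ranges rather than as point orderings.

## Flux magnitudes (mixed model)

Per flux and season, site means are modelled with vegetation type as fixed
effect (cell means) and the data-distribution network as a random
intercept, estimated by REML (statsmodels MixedLM). Estimated type means
and their covariance are recomputed by GLS at the REML variance components
(per-network Sherman–Morrison inversion): away from the boundary this
equals the model output, and it remains positive definite when the
between-network variance estimate hits zero — where the model degenerates
exactly to a one-way ANOVA on site means (tested equivalence).

Denominator degrees of freedom for mixed models have no unique definition;
the default is a residual-type approximation `n − k − (n_networks − 1)`
(configurable), used for CIs, the omnibus Wald F of type-mean equality and
the pairwise contrasts. The omnibus test is suppressed (reported as
missing) when three or more of the seven standard surface classes are
absent. Pairwise contrasts are Bonferroni-adjusted (raw p × C(k,2), capped
at 1). Bowen ratios are H/LE of the estimated type means, displayed at one
decimal, with the conventional "<0" label when LE = 0 and H < 0.

## Seasonality

Daily values are averaged per site and day of year across years (Feb 29
dropped so every year maps to DOY 1–365), then averaged (mean ± s.e.)
across each vegetation type's sites, then smoothed with a centered 15-day
**circular** moving average (DOY 1 neighbors DOY 365, matching the
periodicity of the annual cycle); windows with fewer than 8 present values
yield missing. The smoother is linear and mean-preserving, attenuates a
pure annual harmonic by the closed-form Dirichlet factor
`sin(15π/365)/(15·sin(π/365))` without phase shift, and spreads a
single-day spike over 15 days at 1/15 height — these properties anchor the
regime-detection tolerances.

The summer regime of a smoothed curve is the **longest contiguous run** of
days above 0 (W m⁻² for R_net, H, G; °C for surface temperature) or, for
albedo, below the midpoint of the smoothed curve's annual minimum and
maximum (smoothed, not raw, extremes — raw daily extremes are noise-
dominated). The longest-run rule is robust to brief noise-driven sign flips
in the shoulder seasons and coincides with first/last-crossing on smooth
unimodal curves. Latent heat is excluded by policy: it stays positive
essentially year-round, so a zero threshold carries no seasonal signal.

Offsets are computed at the vegetation-type level (site-level seasonality
is not resolved): `start_offset = regime start − type snow-free date`,
`end_offset = regime end − type snow-onset date`, where type snow dates are
per-site medians over 2000–2020 averaged across the type's sites. Offsets
across types are tested with two-sample Welch t-tests (Satterthwaite df);
degenerate zero-variance equal-mean inputs return t = 0, p = 1.

## Synthetic network generator

The generator produces the statistical structure the pipeline assumes, not
land-surface physics:

* **Annual cycles.** Every non-shortwave variable follows a cosine in DOY
  (`mean + amplitude·cos(2π(d − peak)/365)`) constant within the day, so
  daily, seasonal and climatological means have closed forms that serve as
  oracles. Class profiles (seven classes including glacier) are set to
  realistic Arctic summer magnitudes; the sensible-heat level of each class
  is solved from its target summer Bowen ratio, ordered boreal peat bog
  (0.1) < graminoid (0.6) < wetland (1.1) < erect-shrub (1.5) <
  prostrate-shrub (1.6) among vegetated classes, with negative targets for
  barren and glacier surfaces.
* **Shortwave.** `SW_in` is clear-sky top-of-atmosphere irradiance times a
  fixed transmissivity (0.75), zero at night; `SW_out` is albedo-scaled
  with a snow/snow-free albedo step tied to each site-year's snow
  phenology draw; `LW_out = σ(T_surf + 273.15)⁴`, making the radiative
  identity exact.
* **Contamination.** Additive Gaussian noise per variable (defaults of
  order 10 W m⁻²); contiguous gap runs with geometric lengths injected per
  sensor stream (logger-dropout style); gross outliers beyond the QC
  bounds (radiation > 1400 W m⁻², temperatures < −100 °C) at a small rate;
  a small fraction of records flagged gap-filled; optional replicate
  sensors and duplication of sites under a second network with a small
  sensor offset.
* **Snow and climate.** Site-year snow-free/onset dates are normal draws
  around class means; the daily snow-category series is clean between
  them. Daily climate is the air-temperature cycle plus noise and wet-day
  exponential precipitation.

Deliberately not simulated: spatial correlation between sites, cloud
variability and transmissivity weather, flux footprint effects, energy
balance non-closure, and trends across years. Passing recovery tests
therefore demonstrates that the pipeline's estimators are unbiased and
correctly plumbed under the stated noise/gap/outlier structure — not that
they are robust to every pathology of real tower data.

## Problem sizes and determinism

Tests run the full chain on networks of 10–14 sites × 2 years of hourly
data (a few million records), the recovery experiments on 100 seeded
site-mean replicates, and Monte-Carlo calibrations on 10⁴ replicates; the
acceptance script uses 14 sites × 3 years. All randomness flows from
explicit seeds (`numpy.random.default_rng`); identical configuration and
seed reproduce byte-identical synthetic data.

## Known limitations

* The mixed-model denominator df is an approximation; software packages
  differ here, and published F/p values from other df methods will not
  match exactly (estimates and CIs are unaffected by the choice far from
  small-sample boundaries).
* The all-pairs scheme is limited to 2-predictor models by design; it does
  not generalize to full LMG/Shapley decompositions over larger subsets.
* Snow phenology assumes one dominant snow season per year; multi-modal
  snow regimes (maritime sites) may be flagged missing.
* The potential-shortwave scale ignores terrain shading; normalized fluxes
  at steep sites would be biased low relative to a terrain-aware scale.
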