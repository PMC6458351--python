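# Methods

## Problem and model

The package quantifies how similar an indoor climate is to the outdoor
climate of every cell of a gridded climatology, and where on the globe the
best analogues lie. Both sides are reduced to the same six-variable
seasonal profile — winter mean daily-minimum temperature and mean vapour
pressure, pooled spring/autumn mean temperature and vapour pressure,
summer mean daily-maximum temperature and mean vapour pressure — and
compared with a standardized Euclidean distance

C = sqrt( Σ_k (g_k − h_k)² / S_k² ),  k = 1…6,

with h the focal (indoor) profile, g a grid cell's profile and S_k a
reference standard deviation per variable. The index is dimensionless,
non-negative, zero iff g = h, monotone in each |g_k − h_k|, and invariant
to jointly rescaling a variable in h, g and S_k. With the square root
omitted (configurable `sqrt_mode=False`) the reported values change but
the ordering of cells — and hence every geographic conclusion — does not;
the rooted form is the default because the index is described and used as
a distance. Ties in the ranking are broken lexicographically by
(lat, lon) so results are reproducible bit-for-bit.

Assumptions worth stating: the six variables are treated as independent
axes (no covariance term, as in the climate-analogue literature this
index comes from); seasons are fixed three-month blocks with a hemisphere
flip (DJF = northern winter = southern summer); and a single year of
gridded data is an acceptable stand-in for "current" outdoor climate.

## From raw series to profiles

**Logger cleaning.** Timestamps are taken as local civil time (monthly and
seasonal aggregation is insensitive to sub-day shifts, so no timezone
correction is attempted). Relative humidity is clipped into [0, 100] %
rather than dropped — saturation pegging at ~100 % RH is a common sensor
artifact, and the reading still carries information — while temperatures
outside ±60 °C are dropped as faults. Duplicate timestamps are averaged,
which is deterministic and order-independent.

**Retention rule.** A home is analysed only if its indoor record covers
winter, summer and at least one of spring/autumn. A season counts as
covered when at least one of its calendar months has ≥ 14 distinct days of
data (`minimum_days`, configurable): enough to estimate a monthly mean,
strict enough that a stray day cannot establish a season.

**Monthly aggregation.** Per (year, month): t_mean is the mean of hourly
temperatures; t_min/t_max are means over days of the daily minimum/maximum
hourly temperature; vapour pressure is converted *per hourly observation*
via the Magnus formula and then averaged. The per-observation order
matters because the conversion is convex in T — converting monthly-mean T
and RH instead gives systematically different values, and a regression
test pins the implemented convention.

**Magnus coefficients.** Default a = 6.1094 hPa, b = 17.625, c = 243.04 °C
(the Alduchov–Eskridge fit, sub-0.4 % error over −40…50 °C); the common
WMO variant (6.112/17.62/243.12) is selectable. e_s(0 °C) = a exactly.

**Seasonal pooling.** Months are pooled by calendar month across years
(December joins the following January/February as winter); spring and
autumn aggregates are computed separately and then averaged into one
interseason value (or the single one present is used). "Minimum/maximum
temperature" defaults to the seasonal mean of monthly mean-daily extrema,
matching the tmn/tmx semantics of gridded climatologies; an alternative
reading (min/max of monthly means within the season) is available via
`extrema="monthly_means"` since raw monthly products can lack daily
extrema.

**Scales.** S_k defaults to the within-home sample SD, over the home's
contributing months, of the monthly quantity underlying variable k
(winter months' t_min for winter_tmin, and so on); the mean-home analysis
uses the across-home SD of each profile variable. Sample (n−1) SDs
throughout. Every scale is floored at 0.1 native units (configurable):
thermostat-controlled homes can hold a variable nearly constant, and the
index divides by S_k².

## Grid handling

Grids are long-format (lat, lon, month, t_mean, t_min, t_max, vp) from
either CF-style netCDF (scipy engine, classic format; CRU-style variable
names tmp/tmn/tmx/vap by default, remappable) or CSV; the two readers
round-trip to identical profiles. Cells must sit on the half-degree
lattice (centres at x.25/x.75) unless `any_grid=True`; since no centre
lies on the equator, hemisphere assignment (lat > 0 → north) has no
boundary case. Cells missing any month are excluded — that is how the
land mask and an Antarctica exclusion are expressed, rather than
hard-coded latitude cuts. Missing tmn/tmx fall back to tmp with a loud
warning, degrading extrema to means rather than refusing to run. Vapour
pressure units are declared (`vp_unit` = hPa, Pa, or tenths-of-hPa) and
converted on read.

Country assignment is point-in-polygon of cell centres against GeoJSON
polygons (shapely STRtree), with a nearest-polygon fallback within 0.5°
for coastal centres just offshore, else "unassigned". Modal-country ties
break alphabetically (logged), and "unassigned" never wins a tie against a
real country.

## Ranking and summaries

The analogue scan is exhaustive — ~67k cells × 6 variables is trivial
vectorized work, so no spatial index is used. Per focal profile it reports
the nearest cell (and country), the ranked top-n (default n = 100) with
mean C and SE = sd/√n, the modal country of the top-n, and the least
similar cell (same machinery, reversed end of the sort). The companion
RMSE splits the six variables by physical type: temperature RMSE over
(winter_tmin, interseason_tmean, summer_tmax), vapour-pressure RMSE over
the three seasonal vapour pressures, both unstandardized. The 3+3 grouping
is this package's choice of a physically interpretable companion metric.

Descriptives report min, max, mean and SE of the mean of each profile
variable across homes. The indoor~outdoor regressions are plain OLS with
intercept on pooled month-home pairs within each season (spring and autumn
pooled), using monthly mean temperature and vapour pressure; residual
degrees of freedom are therefore n_pairs − 2. Pooling monthly pairs, not
per-home seasonal values, is what makes the residual d.f. scale with
months × homes. No heteroscedasticity correction is applied.

## Synthetic data: what it emulates, and what it does not

The home generator produces hourly indoor series with a per-home
thermostat setpoint (population mean 21.5 °C, between-home SD 2.5 °C), a
mild indoor seasonal drift (±3 °C, peaking mid-July) and diurnal cycle
(±1 °C), and AR(1) noise (coefficient 0.9 — hour-to-hour thermal inertia)
with stationary SD `setpoint_tightness`; outdoor series carry a
mid-latitude annual cycle (12 ± 12 °C) plus a 5 °C diurnal swing. The
default window is February 2013 – April 2014 at hourly cadence and the
default cohort is 37 homes — the deployment shape the analysis is built
around; these magnitudes reproduce the observed separation between indoor
winter minima (~16 °C) and summer maxima (~27 °C) in lived-in homes.
Months can be deleted per home to create QC-failing cases.

The grid generator places cells on the half-degree lattice with monthly
mean temperature `equator_mean_T − pole_gradient·|lat| + amp(lat)·cos(2π
(month − peak)/12)`, amplitude growing with |lat| and the peak month
flipped across the equator; daily extrema are a fixed ±5 °C half-range,
relative humidity declines linearly with |lat|, and vapour pressure is
derived from the generated T and RH through the same Magnus conversion
the analysis uses, so generator and pipeline are model-consistent. A
closed-form per-cell profile (`expected_cell_profile`) provides an
independent oracle. `plant_analogue` overwrites one cell's months with
their seasonal targets (min = mean = max within each month), making its
profile equal a given target exactly — the ground truth for ranking tests.

What the generator does *not* emulate: real spatial covariance of climate
fields, coastlines/orography, humidity–temperature coupling indoors of
real occupant behaviour, logger dropouts and drift, or interannual
variability. Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic, invariances and plumbing under realistic
magnitudes — not that any particular real-world geographic finding would
be reproduced; that requires the real logger deposit and climatology,
which plug into the same interfaces.

## Numerical choices and degenerate inputs

Float64 throughout; profile aggregation is plain means, so constants are
conserved exactly. Non-finite profile entries or non-positive scales are
hard errors before any distance is computed. Empty cell sets, required
seasons entirely absent, fewer than two homes for across-home statistics,
and zero-variance OLS predictors are hard errors with named messages;
months below the day threshold and sub-2-sample scales degrade gracefully
(omitted / floored, logged). Reader round-trip equality is asserted to
1e-9 after fixed-precision serialization.

## Test and script problem sizes

The suite validates ranking against a naive per-cell oracle on grids of a
few hundred cells, recovers planted analogues across 100 seeds on a
100-cell grid, and runs the end-to-end pipeline on 5 homes × 400 cells;
the acceptance script uses 8 homes (two deliberately failing QC) and a
4 800-cell grid with a 200-replicate slope-recovery simulation. These
sizes exercise every code path in seconds while keeping the exhaustive
scan's cost linear in cells, exactly as it is at full global scale.

## Known limitations

* Single-predictor OLS with no home-level random effects; homes
  contributing more months weigh more in the seasonal regressions.
* The interseason pooling averages spring and autumn aggregates even when
  their month counts differ (each season contributes equally, not each
  month).
* Country assignment uses cell centres only; a cell straddling a border is
  attributed to whichever polygon contains its centre.
* netCDF support is classic-format (netCDF3) via the scipy engine;
  netCDF4/HDF5 files must be converted or exported to the long CSV form
  first.
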