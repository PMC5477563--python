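# Methods

This note records the scientific and numerical choices behind the pipeline:
what each stage assumes, which conventions were genuinely open and how they
were fixed, and what the synthetic tests do and do not demonstrate.

## Monthly climatologies from hourly fields

Monthly temperature extremes are the minimum and maximum of **all hourly
values** in the calendar month, converted K→°C (T − 273.15) at climatology
construction so that all downstream arithmetic is in °C. This differs from
the station-data convention (monthly means of *daily* extremes) used by
interpolated climatologies; hourly reanalysis-style input makes the direct
extreme both simpler and better defined, but users comparing against
daily-extreme products should expect systematically wider diurnal ranges
(BIO2) and more extreme BIO5/BIO6. `hmean` is the plain arithmetic mean of
hourly humidity with no time weighting.

A month must contain at least `min_coverage` (default 0.9) of its hours;
otherwise the reduction fails loudly, naming the month and the observed
fraction. Partial station records are a documented reality (austral-winter
gaps are common), so silent gap-filling is deliberately not offered.

## The 19 variables and the humidity moisture axis

"Quarters" are the 12 cyclically consecutive three-month windows
({Jan,Feb,Mar} … {Dec,Jan,Feb}); extreme windows break ties toward the
earliest start month. This is the rolling-window convention of the R
`dismo::biovars` function, not calendar quarters. BIO4 uses the **sample**
standard deviation (n−1) of the 12 monthly mean temperatures, ×100. The
wettest/driest quarter is ranked by the moisture **sum** (equivalent to the
mean when no month is missing).

BIO15 is 100·σ/μ of the monthly moisture plus `cv_offset`. The
precipitation-oriented convention adds 1 before taking the CV (to guard
against zero-mean precipitation); on kg/kg humidity values an offset of 1
dominates the mean and collapses the CV toward zero, so the package default
is `cv_offset = 0` (the literal CV of the humidity series) with
`cv_offset = 1.0` available for strict emulation of the precipitation code
path. Both behaviours are exercised by tests; neither is claimed to match
any published raster.

Since specific humidity is intensive, the annual and quarterly sums that
the precipitation-style formulas produce have no ecological meaning; the
**ecological rescale** (BIO12/12, BIO16–BIO19 /3) converts them to annual
and quarterly mean humidity. A `rescaled` flag guards against double
application. Rescaling happens **before** integer quantization so no
precision is lost to integer division.

Missing propagation: a NaN in any monthly input blanks all 19 outputs for
that cell-year; BIO3 is additionally undefined where the annual range is
zero, and BIO15 where the offset moisture has zero mean.

Decades partition 1981–2010 as 80s = 1981–1990, 90s = 1991–2000,
00s = 2001–2010, averaged per variable and cell.

## Downscaling: local regularized thin-plate splines

Each target cell center is predicted from its `n_neighbors` (default 12)
nearest source cell centers by a 2-D thin-plate spline (kernel r² log r
plus an affine polynomial part) with the regularization `weight`
(default 0.1) added to the kernel diagonal. Defaults mirror the documented
defaults of the widely used GIS regularized-spline tool; its exact
(proprietary) weight semantics are not reproduced, and numerical equality
with rasters produced by it is nowhere claimed.

Properties that the implementation guarantees and the tests check:

* weight = 0 interpolates exactly through the source points;
* constants and affine trends in (lon, lat) are reproduced exactly for
  *any* weight (they are absorbed by the polynomial part);
* the prediction is a fixed linear functional of the source values, so
  layers sharing a missing-value mask share neighborhoods and the identity
  BIO7 = BIO5 − BIO6 survives interpolation to round-off.

Neighbor search embeds source and target centers on the unit sphere and
queries a k-d tree: chord distance is monotone in great-circle distance, so
the search is great-circle-aware and handles the antimeridian without
duplicating source columns. The spline itself is fitted in plain degree
coordinates with longitudes unwrapped into each neighborhood's frame; no
map projection is applied, and no land/sea mask (the `extent` argument
crops instead).

Near the poles the nearest sources all lie on the last grid row and are
exactly collinear; there the thin-plate system is singular and the
implementation falls back to inverse-distance weighting with a logged
warning. Identical neighbor sets are detected by a 64-bit row hash whose
grouping is verified exactly (with a lexicographic fallback on collision),
and one factorisation per neighborhood is reused across all 19 layers.
Bulk downscaled layers are float32; the single-layer API keeps float64.

## Integer storage and naming

Quantization is value × scale, rounded half-away-from-zero: ×10 for
BIO1–BIO11 (0.1 °C resolution) and ×100 000 for BIO12–BIO19 (10⁻⁵ kg/kg).
Values are stored as int16 with nodata −32768 — except **BIO15**, which is
a coefficient of variation in percent: under the ×100 000 rule any
realistic humidity CV exceeds the int16 range, so BIO15 is stored as int32.
A scaled value outside its integer range raises an overflow error naming
the cell; nothing wraps silently. The round-trip error is bounded by half a
quantum (0.05 °C / 5·10⁻⁶ kg/kg).

GeoTIFFs are single-band, north-up, geographic WGS84 (the convention is
fixed here; the inputs are unprojected lat/lon), with ModelPixelScale /
ModelTiepoint geo-tags, an EPSG:4326 GeoKey directory and a GDAL-style
nodata tag. Names follow `resolution_version_decade_BIOn.tif` with
resolution tokens `10m`, `5m`, `2_5m`; the 513 valid combinations render
and parse bijectively.

## Validation statistics

**Collocation** pairs the nearest cell center's series with a station's
records on their exact common timestamps (6-hourly stations match the
shared hours); a station on a cell edge resolves deterministically to the
lowest row, then column index. No bilinear interpolation: raw cells are
what a reanalysis-versus-station comparison evaluates.

**Regression orientation**: the gridded series is the response, the
station the predictor. This matches reading "the gridded product runs
colder" off a negative intercept with slope below one; the orientation is
switchable by swapping the columns. With noise on the station (predictor)
side, OLS attenuates the slope by var(signal)/(var(signal)+var(noise)) —
recovery of planted slopes to ±0.02 therefore requires the signal variance
to dominate, which the synthetic truth series provide via large seasonal
and diurnal amplitudes (SD ≈ 15 °C, typical of polar station records).

The scalar "bias" is the **interquartile range of the residuals**;
quartiles use linear interpolation between order statistics everywhere
(quantiles, fences, five-number summaries).

**Buffer zones** are squares in degree space of area 1/3 square degree
(side √(1/3) ≈ 0.577°) — the native cell area — centered on stations,
clipped to ±90° latitude and unioned so overlaps are not double-counted.
Raster comparison uses cells whose centers fall in the union; outliers are
residuals outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], and the outlier area
fraction weights cells by cos(latitude).

In the planted-outlier tests the corruption goes into the **response**
raster: predictor-side shifts of ±10 IQR are high-leverage points that
drag the OLS fit through themselves and can leave the displaced residuals
at or below the fence, so they do not measure recovery.

## The synthetic generator

The generator emulates the statistical *shape* of hourly reanalysis fields,
not their physics: a latitudinal lapse from an equatorial mean, an annual
cosine peaking mid-January (southern summer) whose sign flips across the
equator, a diurnal cosine peaking at 14:00 UTC (no local-solar offset — the
phase does not affect monthly extremes), i.i.d. Gaussian hourly noise with
no spatial or temporal correlation, and specific humidity q_ref·exp(c·T)
clipped to [10⁻⁶, 0.04] kg/kg (a crude Clausius–Clapeyron analogue with no
saturation physics or topography). Defaults: 26 °C at the equator,
0.6 °C/° lapse, 10 °C seasonal and 6 °C diurnal amplitude, 1 °C noise,
7.7 g/kg at 0 °C growing 6 %/°C. The calendar is proleptic Gregorian UTC
with leap days and no leap seconds. Cubes are bit-reproducible for a fixed
seed.

Consequently, passing tests demonstrate correctness of the *computations*
(aggregation, window selection, interpolation, quantization, statistics) —
not skill against real atmospheres: there is no weather autocorrelation, no
humidity saturation, no orography, and station records are exactly linear
in their grid cell plus noise.

## Problem sizes and budgets

The end-to-end check runs one full decade (ten years of hourly data) on a
36×18 native grid, one humidity version, downscaled globally to 10, 5 and
2.5 arc-minutes and written as 57 GeoTIFFs — small enough to run routinely
while exercising every stage, including the ~2.3 M, ~9.3 M and ~37 M-cell
target grids. Oracle equivalence uses 1 000 random single-cell
climatologies against an independent per-cell loop implementation;
statistical recoveries use n = 10⁴–10⁵ with fixed seeds.

## Known limitations

* No curvilinear/rotated-pole grids, no sub-hourly data, no quality
  filtering of hourly values before taking extremes.
* The spline is neighborhood-local; long-range structure beyond 12
  neighbors does not inform a prediction, and polar caps fall back to IDW.
* Ordinary-kriging comparison is out of scope; the interpolator is
  pluggable by design but only the regularized TPS ships.
* The degree-space buffer geometry ignores meridian convergence (squares
  shrink in true area toward the poles); the area *fractions* reported are
  cos-latitude weighted, the buffer shapes are not.
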