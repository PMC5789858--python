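# Methods

This note documents the models, conventions, and numerical choices behind
`frostphen`, and what the synthetic-world tests do and do not demonstrate
about real data.

## Calendar and windows

All computation uses a fixed 365-day calendar; Feb 29 samples of
real-calendar inputs are dropped on read.  Day-of-year (DOY) is 1-based
(Jan 1 = 1).  Every date window is a closed integer interval
[start, end].  The northern summer solstice is DOY 173 (June 22); when
splitting growing-season frost days, the solstice day itself belongs to
spring and autumn starts the next day, so the spring + autumn partition
is exact by construction (two closed intervals sharing the solstice would
double-count it).  The "first half year" searched for season start is
DOY 1–182, the second half (season end) 183–365.

## Frost definition

A frost day has daily minimum temperature strictly below 0 °C; a day at
exactly 0.0 °C is not frost.  Daily minima are the minimum over each
day's 3- or 6-hourly samples in the cube's native time coordinate (no
local-solar-time correction — a known approximation for gridded forcing).
Kelvin inputs are detected by value range (> 150) and converted with a
logged warning; no silent unit changes occur elsewhere.

## Synthetic world

The generator produces the study's data classes with known truth:

- **NDVI**: per pixel-year, NDVI(t) = w + A·[σ(k_up(t − SOS)) −
  σ(k_down(t − EOS))] with σ the logistic function, evaluated at the 24
  bimonthly composite midpoints, plus i.i.d. Gaussian composite noise and
  clipping to [−0.2, 1.0].  The inflection-point convention makes the
  true SOS/EOS unambiguous: the curve passes through half amplitude
  exactly at those dates.  Transition slopes default to 0.15/day.
- **T_min**: mean + linear trend − seasonal·cos(2π(DOY − 15)/365.25)
  (coldest mid-January, warmest mid-July) + diurnal·cos(2π(h − 18)/24)
  (coldest 06:00) + AR(1) daily weather noise (stationary sd σ_w, lag-1
  autocorrelation φ) shared by all samples of a day.  The diurnal cycle
  is deterministic so the daily-minimum structure stays analytic.
- **Sites**: random pixels; observed unfolding/senescence are the pixel's
  true SOS/EOS plus Gaussian observation noise, rounded to integer DOY,
  with site-years dropped independently at a missing rate.

Default parameter ranges (each field an independent smooth low-order
random surface, giving the spatial autocorrelation that moving-window
statistics need): baseline SOS 110–140 DOY, EOS 260–290, SOS trend
−0.5..−0.1 d/yr (advancing spring), EOS trend +0.1..+0.5 d/yr, NDVI
winter background 0.05–0.2, amplitude 0.3–0.6, T_min annual mean 2–8 °C,
seasonal amplitude 12–18 °C, diurnal amplitude 3–5 °C, warming
0.015–0.035 °C/yr (≈0.7 °C over 31 years, matching the observed northern
warming of the study period), φ 0.6–0.8, σ_w 2–4 °C, composite noise sd
0.02.  These place the season edges near the freezing line, so frost days
concentrate just after SOS and just before EOS — the regime the analysis
is about.

**What the generator does not emulate**: satellite orbital artifacts,
snow/cloud contamination, spatially correlated weather systems (noise is
independent across pixels), elevation structure, species composition of
pixels, or non-linear phenology–temperature coupling (true SOS/EOS are
prescribed, not driven by the temperature field).  Passing tests
therefore demonstrate the correctness and statistical calibration of the
estimators under the stated model, not their skill on real archives.

## Phenology extraction

Each method reconstructs a 1-day-step seasonal curve from ≥ 20 of the 24
composites, requiring a seasonal amplitude of at least 0.05 NDVI
(configurable; smaller-range pixels are flagged non-seasonal and carry no
dates):

- **hants** — least-squares harmonic series: mean plus 3 harmonics
  (periods 365, 365/2, 365/3), the standard order for a 24-point annual
  series.
- **polyfit** — 6th-order polynomial on a scaled domain.
- **double_logistic** — the 6-parameter model above, fitted by bounded
  nonlinear least squares with analytic Jacobian and up to 5 multi-start
  initializations seeded from slope-scan dates (±15/±30-day jitters);
  the start loop exits early when the fit is essentially exact or an
  extra start no longer improves the SSE by 2%.  SOS/EOS are the model's
  own inflection parameters.
- **piecewise_logistic** — independent 4-parameter sigmoids for the
  rising and falling halves (split at the composite maximum), spliced at
  the peak; SOS/EOS are the extrema of each sigmoid's first derivative,
  i.e. their midpoints.

Dating is climatological-threshold: the multi-year mean composites are
fitted once per method; for the linear methods the dates of maximum
day-to-day increase (DOY 1–182) and decrease (183–365) are found on the
fitted daily curve — only *interior local extrema* of the slope count,
which rejects spurious boundary slopes of the polynomial (Runge edge
wiggles), with the earliest DOY winning ties — and for the logistic
methods the model parameters are used directly.  The fitted NDVI at those
dates becomes the per-pixel thresholds; each year's own fitted curve is
then dated by the first upward crossing of the SOS threshold (DOY 1–182)
and the last downward crossing of the EOS threshold (DOY 183–365),
linearly interpolated and rounded half-up to integer DOY.  Per-year
curves are fitted from that year's composites only; logistic year-fits
are seeded from the pixel's climatological parameters and use 2 starts.

Bimodal pixels (two fitted-curve maxima separated by a trough of ≥ 10% of
the curve amplitude) follow the double-season rules: with two complete
seasons, SOS comes from the first and EOS from the second (the full-year
threshold search yields this directly); when the second season runs past
Dec 31, only the first season counts and the EOS search is truncated at
the trough (and, necessarily, allowed to find descents before mid-year).

The ensemble is the per-date arithmetic mean over methods (minimum 2
valid methods, configurable), rounded half-up; pixel-years violating
SOS < EOS are dropped.  On noiseless synthetic worlds the ensemble dates
land within ~1.5 days of truth on average (the linear methods carry
~5-day biases of opposite signs that largely cancel; the logistic methods
are essentially exact), and within ~2 days at composite noise sd 0.02.

## Decadal statistics

Decades default to 1982–1989, 1990–1999, 2000–2009 (the record starts in
1982; the site comparison ends in 2009) and are configurable.  Decadal
means need ≥ 7 valid years per pixel.  Differences use our own vectorized
Welch (unequal-variance) two-sample t (Welch–Satterthwaite df, two-sided
p from the Student-t survival function), chosen over the pooled test for
robustness to unequal decade variances.  Degenerate pixels: zero variance
in both decades with equal means → p = 1; with unequal means → p = 0.
Hemispheric area fractions and regional means weight pixels by
cos(latitude).  No multiple-testing correction is applied across pixels.

## Attribution

Per draw, one calendar year is sampled uniformly (one year globally, not
per pixel — "held constant" is read as a single field reused for the
whole record); `fix_phenology` applies that year's SOS/EOS field to every
year's temperatures, `fix_temperature` the reverse.  Counts are averaged
over 10 draws; draw seeds derive from a master seed and are recorded in
the output manifest.  The dominant driver per pixel is the scenario with
the larger absolute decadal delta; absolute deltas within 0.1 day are
"mixed".  Additivity of the two scenario deltas is *not* asserted — frost
counting is nonlinear in its inputs — and pixels whose growing season
never reaches frost have both deltas near zero and land in "mixed"; the
recovery tests therefore score dominance over pixels with a material
(≥ 0.5-day) full-pipeline change.

## Spatial association

The temperature covariate of the partial correlations is the
between-decade change in growing-season mean daily T_min (the window
being each pixel-year's season; configurable to annual mean), since a
"temperature change" control needs a concrete statistic.  Windows are
5 × 5 pixels (2.5° at 0.5° resolution), centered on every output cell,
truncated at edges, and require ≥ 10 complete pixels.  The first-order
partial correlation uses the closed form
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) with the t transform on
n − 3 df; control correlations within 1e-6 of ±1 return missing.  The
continental slope is cos-latitude-weighted least squares with a two-sided
t test on n − 2 df.  p-values carry no spatial-autocorrelation
correction.

## Problem sizes and numerical notes

The verification runs use a 16 × 32-pixel, 31-year world for phenology
recovery and 12 × 24-pixel worlds for attribution and association — large
enough for ≥ 100-pixel trend averages, ≥ 280 windows, and sub-0.1-day
Monte-Carlo error on pixel-mean scenario deltas, while keeping the full
four-method extraction to a few minutes on one CPU.  Logistic fits use
ftol 1e-8 and capped function evaluations (120); slope-scan ties break to
the earliest DOY; all reported dates are integer DOY (half-up rounding).
Remapping to coarser grids is the arithmetic mean over each block with a
50% validity requirement.  Missing values propagate as NaN end to end.

## Known limitations

- Site-to-grid matching is containing-cell; nearest-station matching
  within a radius is not implemented beyond the cell lookup.
- The piecewise-logistic splice can be discontinuous at the peak
  composite; dating is unaffected (it uses the sigmoid parameters), but
  the spliced curve should not be used as a smoother.
- An alternative convention defines piecewise-logistic transition dates
  by extrema of the curvature change rate rather than of the first
  derivative; this implementation uses the first-derivative extrema
  (the sigmoid midpoints).
- Scenario draws reuse one year globally; per-pixel draws would change
  the Monte-Carlo error structure but not the expectation.
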