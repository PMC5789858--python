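# frostphen

Analysis pipeline for **growing-season frost-day (GSFD) exposure** on
gridded climate and vegetation data: does a longer growing season expose
northern vegetation to *more* frost, even as warming removes frost days
from the calendar year?

A frost day is a day with minimum air temperature T_min < 0 °C.  The
growing season of each pixel-year is the interval [SOS, EOS] (start/end of
season, day-of-year) read from the seasonal cycle of NDVI.  The pipeline
measures how the count

    GSFD(pixel, year) = #{ d in [SOS, EOS] : T_min(d) < 0 °C }

changed between decades, splits it at the summer solstice (June 22) into
spring (SPR-FD) and autumn (FAL-FD) parts, and separates the two possible
drivers — phenological change (longer seasons) versus temperature change —
with a factorial re-counting experiment and spatial-association
statistics.  It is aimed at land-surface phenologists and ecoclimatologists
who want each stage of such an analysis as tested, reusable code.

## What is implemented

- **Synthetic earth** (`frostphen.synthetic`): gridded NDVI composites
  (24/year, double-logistic seasonality with per-pixel SOS/EOS trends and
  composite noise), 3- or 6-hourly T_min (annual + diurnal cycles, AR(1)
  weather noise, warming trend), and site-level phenology tables — all
  with known truth so every downstream stage can be scored.
- **Phenology extraction** (`frostphen.phenology`): four seasonal-curve
  methods — harmonic series (HANTS-style), 6th-order polynomial, double
  logistic, and a piecewise pair of sigmoids — with climatological
  threshold dating: the multi-year mean curve supplies the dates of
  maximum NDVI increase/decrease (or the logistic models' own inflection
  parameters) and the NDVI values there become thresholds whose crossings
  date each individual year.  Double-growing-season rules and a
  four-method ensemble are included.
- **Frost counting** (`frostphen.frost`): daily minima from sub-daily
  cubes, windowed counts with the solstice or mid-season cutoff, and
  10-day timing histograms from the season edges.
- **Decadal change** (`frostphen.change`): per-pixel Welch tests between
  decades, cos-latitude-weighted area fractions, regional means.
- **Attribution** (`frostphen.attribution`): scenario 1 holds phenology
  at a randomly drawn year while temperature varies; scenario 2 the
  reverse; 10 draws are averaged and each pixel's dominant driver labeled.
- **Spatial association** (`frostphen.association`): 2.5° × 2.5°
  moving-window partial correlations of ΔGSFD with ΔGSL (controlling
  ΔT_min) and with ΔT_min (controlling ΔGSL), 1-day binned change
  densities with quadrant shares, and the continental weighted slope of
  ΔGSFD on ΔGSL.
- **In-situ comparison** (`frostphen.insitu`): PEP725-style site filters
  (leaf unfolding by end of June, senescence from July on, minimum years
  of record) and paired site-vs-satellite decadal deltas.
- **I/O and orchestration** (`frostphen.grid_io`, `frostphen.pipeline`):
  CF-style NetCDF and CSV round-trips, Kelvin auto-conversion, leap-day
  normalization to a 365-day calendar, fine-to-coarse phenology remapping,
  and an end-to-end `pipeline.run(RunConfig)` with a provenance manifest.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
world and write their tables under `results/analysis/`:

```sh
python analysis/01_simulate_world.py
python analysis/02_extract_phenology.py
python analysis/03_count_frost_days.py
python analysis/04_decadal_change.py
python analysis/05_attribute_drivers.py
python analysis/06_spatial_association.py
python analysis/07_insitu_comparison.py
```

On the default 12 × 24-pixel, 1982–2012 world (advancing spring, delaying
autumn, ≈0.8 °C warming) this prints, among other lines:

```
ensemble              sos MAE 1.26  eos MAE 1.65  coverage 100%
mean GSFD: 3.37 days/season (spring 1.64, autumn 1.73)
spring frost concentration: 93% of spring frost days fall within 20 days after SOS
1980s->2000s   gsfd   +1.38   sig+ 17.6%   sig- 0.3%
temperature-only scenario: -0.94 days    phenology-only scenario: +2.14 days
continental slope: +0.260 frost days per GSL day (p = 1.4e-07)
decadal dGSFD 1980s->2000s: in-situ +1.14 ± 1.66, satellite +1.23 (60 pairs)
```

Read: the ensemble dating recovers the generator's true season dates to
~1.5 days; frost days cluster tightly against the season edges; between
the 1980s and the 2000s the growing season gained on average 1.4 frost
days per pixel even though warming alone would have *removed* ~0.9 —
the season extension added ~2.1, dominating the budget — and regions with
faster season extension gained more frost days (positive continental
slope, positive windowed partial correlations), while site-window counts
sit below the satellite-window counts but agree on the sign of change for
92% of matched pairs.

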