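"""Synthetic gridded world with known phenological and climatic truth.

Generates (a) bimonthly NDVI composites whose noiseless seasonal shape is a
double logistic with pixel-specific season start/end and linear decadal
trends, (b) sub-daily minimum-temperature cubes with an annual cycle, a
deterministic diurnal cycle (coldest near 06:00), AR(1) daily weather noise
and a linear warming trend, and (c) PEP725-like site phenology tables with
observation noise and missing years.  Every generator is a pure function of
its arguments including the seed, and every cube carries its TruthGrid so
downstream parameter-recovery tests can compare estimates to truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    DAYS_PER_YEAR,
    N_COMPOSITES,
    TRUTH_FIELDS,
    NdviCube,
    TminCube,
    TruthGrid,
)

__all__ = [
    "DEFAULT_RANGES",
    "gen_truth",
    "gen_ndvi",
    "gen_tmin",
    "gen_insitu",
    "double_logistic",
    "composite_midpoints",
]

#: DOY of the coldest part of the annual T_min cycle (mid-January); the
#: warmest point falls half a period later, in mid/late July.
TMIN_COLDEST_DOY = 15
#: Hour of the diurnal temperature maximum; minimum is 12 h earlier (06:00).
DIURNAL_PEAK_HOUR = 18
#: Default logistic slopes of the seasonal NDVI transitions, 1/day.
GREENUP_SLOPE = 0.15
SENESCENCE_SLOPE = 0.15

#: Default parameter ranges (min, max) for :func:`gen_truth`.  Chosen to
#: produce mid-latitude pixels whose season edges sit near the freezing
#: line so frost days occur in both spring and autumn tails.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "sos0": (110.0, 140.0),
    "eos0": (260.0, 290.0),
    "sos_trend": (-0.5, -0.1),
    "eos_trend": (0.1, 0.5),
    "ndvi_winter": (0.05, 0.2),
    "ndvi_amplitude": (0.3, 0.6),
    "tmin_annual_mean": (2.0, 8.0),
    "tmin_seasonal_amplitude": (12.0, 18.0),
    "tmin_diurnal_amplitude": (3.0, 5.0),
    "tmin_trend": (0.015, 0.035),
    "tmin_ar1": (0.6, 0.8),
    "tmin_noise_sd": (2.0, 4.0),
}


def composite_midpoints() -> np.ndarray:
    """Nominal mid-composite DOYs of the 24 bimonthly composites."""
    i = np.arange(1, N_COMPOSITES + 1)
    return (i - 0.5) * DAYS_PER_YEAR / N_COMPOSITES


def double_logistic(t, winter, amplitude, sos, eos,
                    k_up=GREENUP_SLOPE, k_down=SENESCENCE_SLOPE):
    """Seasonal NDVI curve with inflection points at exactly sos and eos.

    NDVI(t) = winter + amplitude * [sigma(k_up (t - sos)) - sigma(k_down (t - eos))]
    with sigma the standard logistic; at t = sos (resp. eos) the rising
    (falling) sigmoid passes through half amplitude.
    """
    t = np.asarray(t, dtype=float)
    up = 1.0 / (1.0 + np.exp(-k_up * (t - sos)))
    down = 1.0 / (1.0 + np.exp(-k_down * (t - eos)))
    return winter + amplitude * (up - down)


def _smooth_surface(rng: np.random.Generator, n_lat: int, n_lon: int,
                    lo: float, hi: float, n_modes: int = 3) -> np.ndarray:
    """Smooth random surface scaled into [lo, hi].

    Sum of a few low-order 2-D cosine modes with random phases gives
    spatial autocorrelation, so moving-window statistics downstream see
    genuine spatial structure rather than white noise.
    """
    if hi < lo:
        raise ValueError(f"invalid range ({lo}, {hi})")
    if hi == lo:
        return np.full((n_lat, n_lon), float(lo))
    yy, xx = np.meshgrid(np.linspace(0, 1, n_lat, endpoint=False),
                         np.linspace(0, 1, n_lon, endpoint=False),
                         indexing="ij")
    z = np.zeros((n_lat, n_lon))
    for k in range(1, n_modes + 1):
        amp = rng.normal(size=2) / k
        phase = rng.uniform(0, 2 * np.pi, size=2)
        z += amp[0] * np.cos(2 * np.pi * k * yy + phase[0])
        z += amp[1] * np.cos(2 * np.pi * k * xx + phase[1])
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < 1e-12:
        z = np.full_like(z, 0.5)
    else:
        z = (z - zmin) / (zmax - zmin)
    return lo + (hi - lo) * z


def gen_truth(n_lat: int, n_lon: int,
              ranges: dict[str, tuple[float, float]] | None = None,
              seed: int = 0,
              lat_start: float = 60.0, lon_start: float = 0.0,
              resolution: float = 0.5) -> TruthGrid:
    """Draw a TruthGrid of smoothly varying per-pixel parameters.

    ``ranges`` overrides entries of :data:`DEFAULT_RANGES`; each field is
    an independent smooth random surface spanning its (min, max) range.
    Degenerate ranges (min == max) pin the field to that value.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("grid must have at least one pixel")
    r = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValueError(f"unknown truth fields: {sorted(unknown)}")
        r.update(ranges)
    if r["eos0"][0] - r["sos0"][1] < 30:
        raise ValueError(
            "eos0 range must sit >= 30 days above sos0 range "
            f"(got sos0 max {r['sos0'][1]}, eos0 min {r['eos0'][0]})")
    rng = np.random.default_rng(seed)
    fields = {}
    for name in TRUTH_FIELDS:
        lo, hi = r[name]
        fields[name] = _smooth_surface(rng, n_lat, n_lon, lo, hi)
    lat_axis = lat_start - resolution * np.arange(n_lat)
    lon_axis = lon_start + resolution * np.arange(n_lon)
    return TruthGrid(lat_axis=lat_axis, lon_axis=lon_axis, **fields)


def gen_ndvi(truth: TruthGrid, years, noise_sd: float = 0.02,
             seed: int = 0) -> NdviCube:
    """Bimonthly NDVI composites following the double-logistic truth.

    Per pixel and year the noiseless signal is the double logistic with
    inflections at the trend-shifted true SOS/EOS; independent Gaussian
    composite noise of sd ``noise_sd`` is added and values are clipped to
    the physical NDVI range [-0.2, 1.0].
    """
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise ValueError("years must be non-empty")
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be contiguous")
    doys = composite_midpoints()
    sos = truth.sos_truth(years)          # (ny, nlat, nlon)
    eos = truth.eos_truth(years)
    t = doys[None, :, None, None]
    signal = double_logistic(
        t, truth.ndvi_winter[None, None], truth.ndvi_amplitude[None, None],
        sos[:, None], eos[:, None])
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    values = np.clip(signal, -0.2, 1.0)
    return NdviCube(values=values, years=years,
                    composite_midpoint_doy=doys,
                    lat_axis=truth.lat_axis, lon_axis=truth.lon_axis,
                    truth=truth)


def gen_tmin(truth: TruthGrid, years, timestep_hours: int = 3,
             seed: int = 0) -> TminCube:
    """Sub-daily minimum-temperature cube with AR(1) daily weather noise.

    signal(year y, day d, hour h) =
        mean + trend * (y - years[0])
        - seasonal_amplitude * cos(2 pi (d - coldest_doy) / 365.25)
        + diurnal_amplitude * cos(2 pi (h - 18) / 24)      # coldest at 06:00
        + AR(1) daily noise (shared by all samples of the day)

    with the annual cycle bottoming out at ``coldest_doy`` (mid-January)
    and peaking half a period later in July.

    The AR(1) process has stationary sd ``tmin_noise_sd`` and lag-1
    autocorrelation ``tmin_ar1``, drawn independently per pixel at daily
    resolution and broadcast to sub-daily samples.
    """
    if timestep_hours not in (3, 6):
        raise ValueError("timestep_hours must be 3 or 6")
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise ValueError("years must be non-empty")
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be contiguous")
    nlat, nlon = truth.shape
    ny = years.size
    spd = 24 // timestep_hours
    n_days = ny * DAYS_PER_YEAR

    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), ny)           # (n_days,)
    year_off = np.repeat(np.arange(ny), DAYS_PER_YEAR)           # (n_days,)
    seasonal = -np.cos(2 * np.pi * (doy - TMIN_COLDEST_DOY) / 365.25)
    hours = np.arange(spd) * timestep_hours
    diurnal_shape = np.cos(2 * np.pi * (hours - DIURNAL_PEAK_HOUR) / 24.0)

    # daily deterministic part, (n_days, nlat, nlon)
    daily = (truth.tmin_annual_mean[None]
             + truth.tmin_trend[None] * year_off[:, None, None]
             + truth.tmin_seasonal_amplitude[None] * seasonal[:, None, None])

    rng = np.random.default_rng(seed)
    phi = truth.tmin_ar1
    sd = truth.tmin_noise_sd
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    z = rng.standard_normal((n_days, nlat, nlon))
    noise = np.empty_like(z)
    noise[0] = sd * z[0]
    for d in range(1, n_days):
        noise[d] = phi * noise[d - 1] + innov_sd * z[d]
    daily += noise

    # broadcast to sub-daily samples: (n_days, spd, nlat, nlon) -> (time,...)
    values = (daily[:, None]
              + truth.tmin_diurnal_amplitude[None, None]
              * diurnal_shape[None, :, None, None])
    values = values.reshape(n_days * spd, nlat, nlon)
    return TminCube(values=values, years=years,
                    timestep_hours=timestep_hours,
                    lat_axis=truth.lat_axis, lon_axis=truth.lon_axis,
                    truth=truth)


def gen_insitu(truth: TruthGrid, n_sites: int, years,
               obs_noise_sd: float = 3.0, missing_rate: float = 0.2,
               seed: int = 0) -> pd.DataFrame:
    """PEP725-like site table of leaf unfolding / senescence dates.

    Each site sits at a random pixel; per observed year the unfolding date
    is the pixel's true SOS plus Gaussian noise (senescence likewise from
    EOS), rounded to integer DOY.  Site-years are dropped independently
    with probability ``missing_rate``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    years = np.asarray(years, dtype=int)
    rng = np.random.default_rng(seed)
    nlat, nlon = truth.shape
    ilat = rng.integers(0, nlat, size=n_sites)
    ilon = rng.integers(0, nlon, size=n_sites)
    sos = truth.sos_truth(years)
    eos = truth.eos_truth(years)
    rows = []
    for s in range(n_sites):
        iy, ix = ilat[s], ilon[s]
        for j, y in enumerate(years):
            if rng.random() < missing_rate:
                continue
            unfold = sos[j, iy, ix] + rng.normal(0.0, obs_noise_sd)
            senesce = eos[j, iy, ix] + rng.normal(0.0, obs_noise_sd)
            rows.append((f"site{s:04d}", truth.lat_axis[iy],
                         truth.lon_axis[ix], int(y),
                         int(np.floor(unfold + 0.5)),
                         int(np.floor(senesce + 0.5))))
    return pd.DataFrame(
        rows, columns=["site_id", "lat", "lon", "year",
                       "unfold_doy", "senesce_doy"])
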