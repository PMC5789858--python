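"""Frost-day counting inside phenological windows.

A frost day has daily minimum temperature strictly below 0 degC (a day at
exactly 0.0 degC is not frost).  Growing-season frost days (GSFD) are
counted over the closed window [SOS, EOS]; the spring part (SPR-FD) runs
from SOS to the cutoff and the autumn part (FAL-FD) from the day after the
cutoff to EOS, so SPR + FAL = GSFD always.  The cutoff is the northern
summer solstice (DOY 173, June 22 in the fixed 365-day calendar) or,
alternatively, the mid-season day floor((SOS+EOS)/2).
"""

from __future__ import annotations

import numpy as np

from .containers import (
    DAYS_PER_YEAR,
    SOLSTICE_DOY,
    DailyTminGrid,
    FrostCountGrid,
    PhenologyGrid,
    TminCube,
)

__all__ = [
    "daily_min",
    "count_frost_days",
    "split_counts",
    "timing_histograms",
    "count_grid",
]

FROST_THRESHOLD_C = 0.0


def daily_min(cube: TminCube) -> DailyTminGrid:
    """Collapse sub-daily samples to the daily minimum per pixel."""
    spd = cube.samples_per_day
    ntime, nlat, nlon = cube.values.shape
    ny = cube.years.size
    days = cube.values.reshape(ny, DAYS_PER_YEAR, spd, nlat, nlon)
    return DailyTminGrid(values=days.min(axis=2), years=cube.years,
                         lat_axis=cube.lat_axis, lon_axis=cube.lon_axis)


def _frost_cumsum(daily: DailyTminGrid) -> np.ndarray:
    """Prefix sums of the frost indicator along the DOY axis.

    ``cs[:, d]`` counts frost days in DOY 1..d; window counts are then a
    difference of two prefix sums.
    """
    frost = daily.values < FROST_THRESHOLD_C
    cs = np.zeros((daily.values.shape[0], DAYS_PER_YEAR + 1,
                   *daily.values.shape[2:]), dtype=np.int32)
    np.cumsum(frost, axis=1, out=cs[:, 1:])
    return cs


def _window_count(cs, start, end):
    """Vectorized frost count over closed windows [start, end] (arrays).

    ``start``/``end`` are integer DOY arrays broadcastable to the leading
    axes of ``cs``; empty windows (start > end) count zero.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    s = np.clip(start, 1, DAYS_PER_YEAR + 1)
    e = np.clip(end, 0, DAYS_PER_YEAR)
    ny = cs.shape[0]
    grid_shape = cs.shape[2:]
    iy = np.arange(ny)[:, None, None]
    ilat = np.arange(grid_shape[0])[None, :, None]
    ilon = np.arange(grid_shape[1])[None, None, :]
    e_idx = np.broadcast_to(e, (ny, *grid_shape))
    s_idx = np.broadcast_to(s, (ny, *grid_shape))
    cnt = cs[iy, e_idx, ilat, ilon] - cs[iy, s_idx - 1, ilat, ilon]
    return np.where(s_idx > e_idx, 0, cnt)


def count_frost_days(daily: DailyTminGrid, start_doy: int,
                     end_doy: int) -> np.ndarray:
    """Frost days in the closed window [start_doy, end_doy], per year/pixel."""
    if not (1 <= start_doy <= end_doy <= DAYS_PER_YEAR):
        raise ValueError(
            f"invalid window [{start_doy}, {end_doy}]: need "
            f"1 <= start <= end <= {DAYS_PER_YEAR}")
    frost = daily.values < FROST_THRESHOLD_C
    return frost[:, start_doy - 1:end_doy].sum(axis=1)


def _cutoff(sos, eos, mode: str):
    if mode == "solstice":
        return np.full_like(np.asarray(sos, dtype=float), SOLSTICE_DOY)
    if mode == "midseason":
        return np.floor((np.asarray(sos, dtype=float) + eos) / 2.0)
    raise ValueError(f"unknown cutoff mode {mode!r}")


def split_counts(daily: DailyTminGrid, sos, eos,
                 cutoff_mode: str = "solstice"):
    """Spring/autumn frost counts for per-(year, pixel) SOS/EOS fields.

    Spring covers [SOS, min(cutoff, EOS)] (the cutoff day itself is
    spring) and autumn [min(cutoff, EOS)+1, EOS]; if SOS is after the
    cutoff, spring is empty and autumn is the whole season.  Returns
    float arrays with NaN where phenology is missing; the partition
    spr + fal = gsfd holds everywhere by construction.
    """
    sos = np.asarray(sos, dtype=float)
    eos = np.asarray(eos, dtype=float)
    valid = np.isfinite(sos) & np.isfinite(eos)
    s = np.where(valid, sos, 1).astype(int)
    e = np.where(valid, eos, 1).astype(int)
    if np.any(valid & (s >= e)):
        raise ValueError("split_counts requires sos < eos where defined")
    c = np.where(valid, _cutoff(s, e, cutoff_mode), 1).astype(int)
    cs = _frost_cumsum(daily)
    spr_end = np.minimum(c, e)
    spr = _window_count(cs, s, spr_end)          # empty when sos > cutoff
    fal = _window_count(cs, np.maximum(spr_end + 1, s), e)
    spr = np.where(valid, spr, np.nan)
    fal = np.where(valid, fal, np.nan)
    return spr, fal


def timing_histograms(daily: DailyTminGrid, sos, eos,
                      cutoff_mode: str = "solstice", bin_days: int = 10):
    """Timing of frost days relative to the season edges, 10-day bins.

    Spring frost days are binned by days elapsed since SOS ([0,10),
    [10,20), ...), autumn frost days by days remaining until EOS, each
    restricted to its side of the cutoff; bins are summed over all valid
    pixel-years.  Bin sums equal the summed spring/autumn counts.
    """
    sos = np.asarray(sos, dtype=float)
    eos = np.asarray(eos, dtype=float)
    frost = daily.values < FROST_THRESHOLD_C     # (ny, 365, nlat, nlon)
    doy = np.arange(1, DAYS_PER_YEAR + 1)[None, :, None, None]
    valid = (np.isfinite(sos) & np.isfinite(eos))[:, None]
    s = np.where(np.isfinite(sos), sos, 9999)[:, None]
    e = np.where(np.isfinite(eos), eos, -9999)[:, None]
    c = np.where(valid, _cutoff(s, e, cutoff_mode), 0)
    spr_end = np.minimum(c, e)
    in_spring = valid & frost & (doy >= s) & (doy <= spr_end)
    in_autumn = valid & frost & (doy > spr_end) & (doy >= s) & (doy <= e)

    n_bins = int(np.ceil(DAYS_PER_YEAR / bin_days))
    hist_sos = np.zeros(n_bins, dtype=np.int64)
    hist_eos = np.zeros(n_bins, dtype=np.int64)
    off_s = ((doy - s) // bin_days).astype(int)
    off_e = ((e - doy) // bin_days).astype(int)
    np.add.at(hist_sos, np.clip(off_s, 0, n_bins - 1)[in_spring], 1)
    np.add.at(hist_eos, np.clip(off_e, 0, n_bins - 1)[in_autumn], 1)
    return hist_sos, hist_eos


def count_grid(daily: DailyTminGrid, phen: PhenologyGrid,
               cutoff_mode: str = "solstice",
               hist_bin_days: int = 10) -> FrostCountGrid:
    """Full per-pixel, per-year frost accounting for a phenology grid."""
    if daily.values.shape[0] != phen.sos.shape[0]:
        raise ValueError("daily temperatures and phenology disagree on years")
    if daily.values.shape[2:] != phen.sos.shape[1:]:
        raise ValueError("daily temperatures and phenology disagree on grid")
    spr, fal = split_counts(daily, phen.sos, phen.eos, cutoff_mode)
    gsfd = spr + fal
    hist_sos, hist_eos = timing_histograms(
        daily, phen.sos, phen.eos, cutoff_mode, hist_bin_days)
    return FrostCountGrid(gsfd=gsfd, spr_fd=spr, fal_fd=fal,
                          years=phen.years, lat_axis=phen.lat_axis,
                          lon_axis=phen.lon_axis, cutoff_mode=cutoff_mode,
                          hist_after_sos=hist_sos, hist_before_eos=hist_eos,
                          hist_bin_days=hist_bin_days)
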