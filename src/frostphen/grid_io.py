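"""NetCDF/CSV input-output and grid harmonization.

Conventions: CF-style dims ``(time, lat, lon)`` for temperature cubes
(variable ``tmin`` in "degC" or "K"; Kelvin is auto-detected by value range
and converted with a logged warning) and ``(year, composite, lat, lon)``
for NDVI cubes (variable ``ndvi``, unitless).  Real-calendar inputs have
their Feb 29 samples dropped on read so every year holds exactly 365 days.
Phenology grids written here carry ``sos``, ``eos``, ``gsl`` variables and
a ``method`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .containers import (
    DAYS_PER_YEAR,
    NdviCube,
    PhenologyGrid,
    TminCube,
)

logger = logging.getLogger(__name__)

_AXIS_TOL = 1e-6
#: Values above this are taken to be Kelvin and converted to Celsius.
_KELVIN_FLOOR = 150.0


@dataclass
class GridSpec:
    """Uniform cell-center lat/lon grid."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray

    def __post_init__(self):
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        for name, ax in (("lat", self.lat_axis), ("lon", self.lon_axis)):
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(np.abs(d - d[0]) > _AXIS_TOL):
                    raise ValueError(f"non-uniform {name} axis")

    @property
    def resolution(self) -> float:
        ax = self.lat_axis if self.lat_axis.size > 1 else self.lon_axis
        if ax.size < 2:
            raise ValueError("cannot infer resolution from a 1-cell axis")
        return float(abs(np.diff(ax)[0]))


def _require(ds: xr.Dataset, names: tuple[str, ...]) -> None:
    for n in names:
        if n not in ds.variables and n not in ds.dims:
            raise ValueError(f"dataset is missing required axis/variable {n!r}")


# ---------------------------------------------------------------- T_min ---

def write_tmin(cube: TminCube, path) -> None:
    ds = xr.Dataset(
        {"tmin": (("time", "lat", "lon"), cube.values,
                  {"units": "degC", "long_name": "daily-minimum proxy air temperature"})},
        coords={"time": np.arange(cube.values.shape[0]),
                "lat": ("lat", cube.lat_axis, {"units": "degrees_north"}),
                "lon": ("lon", cube.lon_axis, {"units": "degrees_east"})},
        attrs={"timestep_hours": int(cube.timestep_hours),
               "start_year": int(cube.years[0]),
               "n_years": int(cube.years.size),
               "calendar": "365_day"},
    )
    ds.to_netcdf(path)


def _drop_leap_days(ds: xr.Dataset) -> xr.Dataset:
    t = ds["time"]
    try:
        is_leap = (t.dt.month == 2) & (t.dt.day == 29)
    except (TypeError, AttributeError):
        return ds
    if bool(is_leap.any()):
        n = int(is_leap.sum())
        logger.info("dropping %d Feb-29 samples to a 365-day calendar", n)
        ds = ds.sel(time=~is_leap)
    return ds


def read_tmin(path, variable: str = "tmin") -> TminCube:
    """Read a sub-daily minimum-temperature cube.

    Accepts either the package's own noleap layout (integer time index plus
    ``timestep_hours``/``start_year`` attributes) or a real-calendar file
    with a datetime time axis, whose Feb 29 samples are dropped.
    """
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    if variable not in ds:
        raise ValueError(f"variable {variable!r} not found in {path}")
    _require(ds, ("lat", "lon", "time"))
    ds = _drop_leap_days(ds)
    da = ds[variable]
    if tuple(da.dims) != ("time", "lat", "lon"):
        raise ValueError(f"{variable!r} must have dims (time, lat, lon), "
                         f"got {da.dims}")
    values = da.values.astype(float)
    units = da.attrs.get("units", "")
    if units in ("K", "kelvin", "Kelvin") or (
            units == "" and np.nanmean(values) > _KELVIN_FLOOR):
        logger.warning("converting %r from Kelvin to Celsius", variable)
        values = values - 273.15
    GridSpec(ds["lat"].values, ds["lon"].values)  # validates uniformity
    if "timestep_hours" in ds.attrs:
        step = int(ds.attrs["timestep_hours"])
        y0 = int(ds.attrs["start_year"])
        ny = int(ds.attrs["n_years"])
        years = np.arange(y0, y0 + ny)
    else:
        t = ds["time"]
        hours = (t.values[1] - t.values[0]) / np.timedelta64(1, "h")
        step = int(round(float(hours)))
        years = np.unique(t.dt.year.values)
    return TminCube(values=values, years=years, timestep_hours=step,
                    lat_axis=ds["lat"].values, lon_axis=ds["lon"].values)


# ----------------------------------------------------------------- NDVI ---

def write_ndvi(cube: NdviCube, path) -> None:
    ds = xr.Dataset(
        {"ndvi": (("year", "composite", "lat", "lon"), cube.values,
                  {"units": "1", "long_name": "bimonthly composite NDVI"})},
        coords={"year": cube.years,
                "composite": np.arange(1, cube.values.shape[1] + 1),
                "composite_midpoint_doy": ("composite",
                                           cube.composite_midpoint_doy),
                "lat": ("lat", cube.lat_axis, {"units": "degrees_north"}),
                "lon": ("lon", cube.lon_axis, {"units": "degrees_east"})},
    )
    ds.to_netcdf(path)


def read_ndvi(path, variable: str = "ndvi") -> NdviCube:
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    if variable not in ds:
        raise ValueError(f"variable {variable!r} not found in {path}")
    _require(ds, ("lat", "lon", "year", "composite_midpoint_doy"))
    GridSpec(ds["lat"].values, ds["lon"].values)
    return NdviCube(values=ds[variable].values.astype(float),
                    years=ds["year"].values,
                    composite_midpoint_doy=ds["composite_midpoint_doy"].values,
                    lat_axis=ds["lat"].values, lon_axis=ds["lon"].values)


# ------------------------------------------------------------ phenology ---

def write_phenology(phen: PhenologyGrid, path) -> None:
    ds = xr.Dataset(
        {"sos": (("year", "lat", "lon"), phen.sos, {"units": "day of year"}),
         "eos": (("year", "lat", "lon"), phen.eos, {"units": "day of year"}),
         "gsl": (("year", "lat", "lon"), phen.gsl, {"units": "days"})},
        coords={"year": phen.years,
                "lat": ("lat", phen.lat_axis, {"units": "degrees_north"}),
                "lon": ("lon", phen.lon_axis, {"units": "degrees_east"})},
        attrs={"method": phen.method},
    )
    ds.to_netcdf(path)


def read_phenology(path) -> PhenologyGrid:
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    _require(ds, ("lat", "lon", "year"))
    return PhenologyGrid(sos=ds["sos"].values, eos=ds["eos"].values,
                         years=ds["year"].values,
                         lat_axis=ds["lat"].values, lon_axis=ds["lon"].values,
                         method=ds.attrs.get("method", "ensemble"))


def remap_phenology(fine: PhenologyGrid, block: int,
                    min_valid_fraction: float = 0.5) -> PhenologyGrid:
    """Aggregate a fine phenology grid onto a coarser nested grid.

    Coarse SOS/EOS are the arithmetic mean of the valid fine cells inside
    each ``block x block`` tile (e.g. block=6 for 1/12 deg -> 0.5 deg); a
    coarse cell is missing where fewer than ``min_valid_fraction`` of its
    fine cells are valid.  block=1 is the identity.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    ny, nlat, nlon = fine.sos.shape
    if nlat % block or nlon % block:
        raise ValueError(
            f"fine grid ({nlat} x {nlon}) does not nest in blocks of {block}")
    if block == 1:
        return PhenologyGrid(sos=fine.sos.copy(), eos=fine.eos.copy(),
                             years=fine.years, lat_axis=fine.lat_axis,
                             lon_axis=fine.lon_axis, method=fine.method)

    def agg(a):
        b = a.reshape(ny, nlat // block, block, nlon // block, block)
        valid = np.isfinite(b)
        nvalid = valid.sum(axis=(2, 4))
        with np.errstate(invalid="ignore"):
            mean = np.nansum(np.where(valid, b, 0.0), axis=(2, 4)) / nvalid
        mean[nvalid < min_valid_fraction * block * block] = np.nan
        return mean

    lat = fine.lat_axis.reshape(nlat // block, block).mean(axis=1)
    lon = fine.lon_axis.reshape(nlon // block, block).mean(axis=1)
    return PhenologyGrid(sos=agg(fine.sos), eos=agg(fine.eos),
                         years=fine.years, lat_axis=lat, lon_axis=lon,
                         method=fine.method)


# ----------------------------------------------------- derived products ---

def write_frost_counts(counts, path) -> None:
    """FrostCountGrid as NetCDF: integer count fields plus timing bins."""
    nbin = counts.hist_after_sos.size
    ds = xr.Dataset(
        {"gsfd": (("year", "lat", "lon"), counts.gsfd),
         "spr_fd": (("year", "lat", "lon"), counts.spr_fd),
         "fal_fd": (("year", "lat", "lon"), counts.fal_fd),
         "hist_after_sos": (("bin",), counts.hist_after_sos),
         "hist_before_eos": (("bin",), counts.hist_before_eos)},
        coords={"year": counts.years,
                "bin": np.arange(nbin),
                "lat": ("lat", counts.lat_axis),
                "lon": ("lon", counts.lon_axis)},
        attrs={"cutoff_mode": counts.cutoff_mode,
               "hist_bin_days": counts.hist_bin_days},
    )
    ds.to_netcdf(path)


def read_frost_counts(path):
    from .containers import FrostCountGrid
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    return FrostCountGrid(
        gsfd=ds["gsfd"].values, spr_fd=ds["spr_fd"].values,
        fal_fd=ds["fal_fd"].values, years=ds["year"].values,
        lat_axis=ds["lat"].values, lon_axis=ds["lon"].values,
        cutoff_mode=ds.attrs.get("cutoff_mode", "solstice"),
        hist_after_sos=ds["hist_after_sos"].values,
        hist_before_eos=ds["hist_before_eos"].values,
        hist_bin_days=int(ds.attrs.get("hist_bin_days", 10)))


def write_change_map(cm, path) -> None:
    ds = xr.Dataset(
        {"delta": (("lat", "lon"), cm.delta),
         "p_value": (("lat", "lon"), cm.p_value),
         "significant": (("lat", "lon"), cm.significant.astype(np.int8))},
        coords={"lat": ("lat", cm.lat_axis), "lon": ("lon", cm.lon_axis)},
        attrs={"alpha": cm.alpha, "n1": cm.n1, "n2": cm.n2},
    )
    ds.to_netcdf(path)


def read_change_map(path):
    from .containers import ChangeMap
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    return ChangeMap(delta=ds["delta"].values, p_value=ds["p_value"].values,
                     lat_axis=ds["lat"].values, lon_axis=ds["lon"].values,
                     alpha=float(ds.attrs.get("alpha", 0.05)),
                     n1=int(ds.attrs.get("n1", 0)),
                     n2=int(ds.attrs.get("n2", 0)))


def write_truth(truth, path) -> None:
    """Persist a TruthGrid so downstream scripts can score estimates."""
    from .containers import TRUTH_FIELDS
    ds = xr.Dataset(
        {f: (("lat", "lon"), getattr(truth, f)) for f in TRUTH_FIELDS},
        coords={"lat": ("lat", truth.lat_axis),
                "lon": ("lon", truth.lon_axis)},
    )
    ds.to_netcdf(path)


def read_truth(path):
    from .containers import TRUTH_FIELDS, TruthGrid
    with xr.open_dataset(path, decode_timedelta=False) as ds:
        ds = ds.load()
    return TruthGrid(lat_axis=ds["lat"].values, lon_axis=ds["lon"].values,
                     **{f: ds[f].values for f in TRUTH_FIELDS})


# ----------------------------------------------------------- site table ---

_SITE_COLUMNS = ("site_id", "lat", "lon", "year", "unfold_doy", "senesce_doy")


def write_site_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_site_table(path) -> pd.DataFrame:
    """Read a PEP725-like site phenology CSV, reporting bad rows by line."""
    df = pd.read_csv(path, dtype={"site_id": str})
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table is missing columns {sorted(missing)}")
    errors = []
    for col in ("year", "unfold_doy", "senesce_doy"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        raw_present = df[col].notna()
        bad = raw_present & coerced.isna()
        # +2: header line plus 1-based numbering
        errors.extend(f"line {i + 2}: bad {col}={df[col][i]!r}"
                      for i in df.index[bad])
        df[col] = coerced
    if errors:
        raise ValueError("malformed site table rows: " + "; ".join(errors))
    for col in ("year", "unfold_doy", "senesce_doy"):
        df[col] = df[col].astype("Int64")
    df["year"] = df["year"].astype(int)
    return df[list(_SITE_COLUMNS)]
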