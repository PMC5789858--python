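"""Shared in-memory containers for the gridded frost-phenology analysis.

All cubes live on a fixed 365-day calendar (no leap days); day-of-year
(DOY) is 1-based with Jan 1 = 1, and all date windows are closed integer
intervals [start_doy, end_doy].  Latitude/longitude axes are cell-center
coordinates in degrees.  Missing values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DAYS_PER_YEAR = 365
#: June 22 in the fixed 365-day calendar; the northern summer solstice used
#: to split growing-season frost days into spring and autumn parts.
SOLSTICE_DOY = 173
#: DOY 1-182 is the "first half year" searched for SOS; 183-365 for EOS.
HALF_YEAR_SPLIT = 182
#: Number of NDVI composites per year (bimonthly compositing).
N_COMPOSITES = 24

TRUTH_FIELDS = (
    "sos0",
    "eos0",
    "sos_trend",
    "eos_trend",
    "ndvi_winter",
    "ndvi_amplitude",
    "tmin_annual_mean",
    "tmin_seasonal_amplitude",
    "tmin_diurnal_amplitude",
    "tmin_trend",
    "tmin_ar1",
    "tmin_noise_sd",
)


def _as_grid(x, shape) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ValueError(f"field shape {a.shape} != grid shape {shape}")
    return a


@dataclass
class TruthGrid:
    """Per-pixel true parameters of the synthetic world.

    ``sos0``/``eos0`` are baseline season start/end DOYs in the first year;
    ``sos_trend``/``eos_trend`` are days/year (negative SOS trend =
    advancing spring).  Temperature parameters define the deterministic
    annual + diurnal cycle, a linear warming trend (degC/year), and the
    AR(1) daily weather noise (lag-1 autocorrelation ``tmin_ar1``,
    stationary sd ``tmin_noise_sd``).
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    sos0: np.ndarray
    eos0: np.ndarray
    sos_trend: np.ndarray
    eos_trend: np.ndarray
    ndvi_winter: np.ndarray
    ndvi_amplitude: np.ndarray
    tmin_annual_mean: np.ndarray
    tmin_seasonal_amplitude: np.ndarray
    tmin_diurnal_amplitude: np.ndarray
    tmin_trend: np.ndarray
    tmin_ar1: np.ndarray
    tmin_noise_sd: np.ndarray

    def __post_init__(self):
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        shape = self.shape
        for name in TRUTH_FIELDS:
            setattr(self, name, _as_grid(getattr(self, name), shape))
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_axis.size, self.lon_axis.size)

    def validate(self) -> None:
        if np.any(self.sos0 <= 0) or np.any(self.eos0 > DAYS_PER_YEAR + 1):
            raise ValueError("sos0/eos0 outside (0, 366]")
        if np.any(self.eos0 - self.sos0 < 30):
            raise ValueError("eos0 - sos0 must be >= 30 days everywhere")
        if np.any(self.ndvi_winter + self.ndvi_amplitude > 1.0 + 1e-12):
            raise ValueError("ndvi_winter + ndvi_amplitude exceeds 1.0")
        if np.any(self.ndvi_amplitude <= 0):
            raise ValueError("ndvi_amplitude must be positive")
        if np.any((self.tmin_ar1 < 0) | (self.tmin_ar1 >= 1)):
            raise ValueError("tmin_ar1 must lie in [0, 1)")
        for name in ("tmin_seasonal_amplitude", "tmin_diurnal_amplitude",
                     "tmin_noise_sd"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")

    def sos_truth(self, years: np.ndarray) -> np.ndarray:
        """True SOS per (year, lat, lon) under the linear trend."""
        years = np.asarray(years)
        off = (years - years[0])[:, None, None]
        return self.sos0[None] + self.sos_trend[None] * off

    def eos_truth(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years)
        off = (years - years[0])[:, None, None]
        return self.eos0[None] + self.eos_trend[None] * off


@dataclass
class NdviCube:
    """Bimonthly NDVI composites, dims (year, composite, lat, lon)."""

    values: np.ndarray
    years: np.ndarray
    composite_midpoint_doy: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    truth: TruthGrid | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.composite_midpoint_doy = np.asarray(
            self.composite_midpoint_doy, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        ny, nc, nlat, nlon = self.values.shape
        if nc != N_COMPOSITES:
            raise ValueError(f"expected {N_COMPOSITES} composites, got {nc}")
        if ny != self.years.size:
            raise ValueError("year axis mismatch")
        if np.any(np.diff(self.composite_midpoint_doy) <= 0):
            raise ValueError("composite midpoints must be strictly increasing")
        if (nlat, nlon) != (self.lat_axis.size, self.lon_axis.size):
            raise ValueError("spatial axes mismatch")


@dataclass
class TminCube:
    """Sub-daily minimum-temperature proxy in degC, dims (time, lat, lon).

    The time axis covers ``len(years) * 365`` complete days at
    ``timestep_hours`` (3 or 6) resolution; sample ``k`` of day ``d``
    is nominally at hour ``k * timestep_hours``.
    """

    values: np.ndarray
    years: np.ndarray
    timestep_hours: int
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    truth: TruthGrid | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        if self.timestep_hours not in (3, 6):
            raise ValueError("timestep_hours must be 3 or 6")
        spd = self.samples_per_day
        ntime = self.values.shape[0]
        if ntime % spd != 0:
            raise ValueError("time axis contains a partial day")
        if ntime != self.years.size * DAYS_PER_YEAR * spd:
            raise ValueError("time axis does not cover whole calendar years")

    @property
    def samples_per_day(self) -> int:
        return 24 // self.timestep_hours

    @property
    def n_days(self) -> int:
        return self.values.shape[0] // self.samples_per_day


@dataclass
class DailyTminGrid:
    """Daily minimum temperature, dims (year, doy, lat, lon), degC."""

    values: np.ndarray
    years: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        if self.values.shape[1] != DAYS_PER_YEAR:
            raise ValueError("daily grid must have 365 DOY slots")
        if self.values.shape[0] != self.years.size:
            raise ValueError("year axis mismatch")


@dataclass
class PhenologyGrid:
    """Per-pixel, per-year SOS/EOS dates (integer DOY stored as float, NaN
    where the pixel-year could not be dated)."""

    sos: np.ndarray
    eos: np.ndarray
    years: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    method: str = "ensemble"

    def __post_init__(self):
        self.sos = np.asarray(self.sos, dtype=float)
        self.eos = np.asarray(self.eos, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        if self.sos.shape != self.eos.shape:
            raise ValueError("sos/eos shape mismatch")
        both = np.isfinite(self.sos) & np.isfinite(self.eos)
        if np.any(self.sos[both] >= self.eos[both]):
            raise ValueError("sos must be < eos wherever both are defined")

    @property
    def gsl(self) -> np.ndarray:
        return self.eos - self.sos


@dataclass
class FrostCountGrid:
    """Frost-day counts inside phenological windows.

    ``gsfd``/``spr_fd``/``fal_fd`` are per (year, lat, lon); NaN marks
    missing phenology.  ``hist_after_sos``/``hist_before_eos`` aggregate
    the timing of spring/autumn frost days into 10-day bins measured from
    SOS forward and EOS backward, summed over all valid pixel-years.
    """

    gsfd: np.ndarray
    spr_fd: np.ndarray
    fal_fd: np.ndarray
    years: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    cutoff_mode: str = "solstice"
    hist_after_sos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hist_before_eos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hist_bin_days: int = 10


@dataclass
class ChangeMap:
    """Between-decade difference map with per-pixel Welch test results."""

    delta: np.ndarray
    p_value: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    alpha: float = 0.05
    n1: int = 0
    n2: int = 0

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.p_value) & (self.p_value < self.alpha)
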