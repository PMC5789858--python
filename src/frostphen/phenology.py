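"""Satellite-style phenology extraction from bimonthly NDVI composites.

Four curve-fitting methods reconstruct the seasonal NDVI trajectory at a
1-day step: a harmonic series (``hants``), a 6th-order polynomial
(``polyfit``), a 6-parameter double logistic (``double_logistic``) and a
pair of independently fitted sigmoids (``piecewise_logistic``).  Dating
follows the climatological-threshold scheme: the multi-year mean curve
yields the day of maximum NDVI increase in the first half year (SOS) and
maximum decrease in the second half (EOS) — for the logistic methods these
transition dates are the model's own inflection parameters — and the NDVI
values attained there become thresholds whose first upward / last downward
crossing dates each individual year.  Per-pixel dates from the four
methods are averaged into an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .containers import DAYS_PER_YEAR, HALF_YEAR_SPLIT, NdviCube, PhenologyGrid

__all__ = [
    "METHODS",
    "SeasonalCurve",
    "fit_curve",
    "climatological_dates",
    "annual_dates",
    "resolve_double_season",
    "ensemble_phenology",
    "extract_phenology",
]

METHODS = ("hants", "polyfit", "double_logistic", "piecewise_logistic")

#: Pixels whose composite range (max - min) falls below this NDVI amplitude
#: are flagged non-seasonal and carry no phenology dates.
DEFAULT_AMPLITUDE_FLOOR = 0.05
_N_HARMONICS = 3
_POLY_DEGREE = 6
_DOY_GRID = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class SeasonalCurve:
    """A fitted 1-day-step seasonal NDVI trajectory for one pixel-year."""

    doy_grid: np.ndarray
    fitted_ndvi: np.ndarray
    method: str
    seasonal: bool = True
    converged: bool = True
    residual_sd: float = np.nan
    #: Model-defined transition dates (double/piecewise logistic only).
    model_sos: float | None = None
    model_eos: float | None = None


# ------------------------------------------------------------- fitting ---

def _harmonic_design(t: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)]
    for k in range(1, _N_HARMONICS + 1):
        w = 2 * np.pi * k * t / DAYS_PER_YEAR
        cols += [np.cos(w), np.sin(w)]
    return np.column_stack(cols)


def _poly_design(t: np.ndarray) -> np.ndarray:
    # scaled to [-1, 1] for conditioning
    x = (t - (DAYS_PER_YEAR + 1) / 2) / (DAYS_PER_YEAR / 2)
    return np.vander(x, _POLY_DEGREE + 1, increasing=True)


def linear_method_projector(doys: np.ndarray, method: str) -> np.ndarray:
    """Matrix P (365 x n_composites) mapping composites to daily curves.

    Valid for the two linear methods when all composites are present; the
    same projector applies to every pixel-year, which makes gridded
    extraction a single matrix product.
    """
    design = {"hants": _harmonic_design, "polyfit": _poly_design}[method]
    X = design(np.asarray(doys, dtype=float))
    Xd = design(_DOY_GRID)
    return Xd @ np.linalg.pinv(X)


def _slope_scan_init(doys: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Crude SOS/EOS guesses: max increase/decrease of the raw composites."""
    dv = np.diff(v) / np.diff(doys)
    mid = 0.5 * (doys[:-1] + doys[1:])
    first = mid <= HALF_YEAR_SPLIT
    sos = mid[first][np.argmax(dv[first])] if np.any(first) else 120.0
    second = mid > HALF_YEAR_SPLIT
    eos = mid[second][np.argmin(dv[second])] if np.any(second) else 270.0
    return float(sos), float(eos)


def _double_logistic_model(p, t):
    w, a, sos, ks, eos, ka = p
    return w + a * (1.0 / (1.0 + np.exp(-ks * (t - sos)))
                    - 1.0 / (1.0 + np.exp(-ka * (t - eos))))


def _double_logistic_jac(p, t):
    w, a, sos, ks, eos, ka = p
    s1 = 1.0 / (1.0 + np.exp(-ks * (t - sos)))
    s2 = 1.0 / (1.0 + np.exp(-ka * (t - eos)))
    d1 = s1 * (1 - s1)
    d2 = s2 * (1 - s2)
    return np.column_stack([
        np.ones_like(t), s1 - s2,
        -a * ks * d1, a * (t - sos) * d1,
        a * ka * d2, -a * (t - eos) * d2,
    ])


def _fit_double_logistic(doys, v, init=None, n_starts=5, ftol=1e-8):
    """Bounded nonlinear least squares with multi-start initialization.

    Starts are seeded from slope-scan (or caller-supplied) transition
    dates plus jittered variants; the loop stops early when the fit is
    essentially exact or when an extra start no longer improves the best
    sum of squares by more than 2%.
    """
    w0, a0 = float(v.min()), float(max(v.max() - v.min(), 0.05))
    if init is None:
        sos0, eos0 = _slope_scan_init(doys, v)
    else:
        sos0, eos0 = init
    lb = [-0.3, 0.01, 1.0, 0.01, 60.0, 0.01]
    ub = [1.0, 1.5, 300.0, 2.0, 400.0, 2.0]
    starts = [(sos0, eos0, 0.15), (sos0 - 15, eos0 + 15, 0.1),
              (sos0 + 15, eos0 - 15, 0.2), (sos0, eos0, 0.05),
              (sos0 - 30, eos0 + 30, 0.3)][:n_starts]
    best = None
    var = float(np.var(v)) * v.size
    for s0, e0, k0 in starts:
        p0 = np.clip([w0, a0, s0, k0, e0, k0], lb, ub)
        try:
            res = least_squares(
                lambda p: _double_logistic_model(p, doys) - v, p0,
                jac=lambda p: _double_logistic_jac(p, doys),
                bounds=(lb, ub), ftol=ftol, xtol=1e-10, max_nfev=120)
        except Exception:
            continue
        improved = best is None or res.cost < 0.98 * best.cost
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < max(1e-10, 1e-4 * var):
            break
        if not improved:
            break
    if best is None:
        return None
    return best


def _sigmoid_half(p, t, rising):
    c, a, m, k = p
    sign = 1.0 if rising else -1.0
    return c + a / (1.0 + np.exp(-sign * k * (t - m)))


def _sigmoid_half_jac(p, t, rising):
    c, a, m, k = p
    sign = 1.0 if rising else -1.0
    s = 1.0 / (1.0 + np.exp(-sign * k * (t - m)))
    d = s * (1 - s)
    return np.column_stack([
        np.ones_like(t), s, -a * sign * k * d, a * sign * (t - m) * d,
    ])


def _fit_half_sigmoid(doys, v, rising, m0):
    c0 = float(v.min())
    a0 = float(max(v.max() - v.min(), 0.05))
    lb = [-0.3, 0.01, 1.0, 0.01]
    ub = [1.0, 1.5, 400.0, 2.0]
    p0 = np.clip([c0, a0, m0, 0.15], lb, ub)
    try:
        return least_squares(
            lambda p: _sigmoid_half(p, doys, rising) - v, p0,
            jac=lambda p: _sigmoid_half_jac(p, doys, rising),
            bounds=(lb, ub), ftol=1e-8, xtol=1e-10, max_nfev=100)
    except Exception:
        return None


def fit_curve(doys, values, method: str,
              amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
              init: tuple[float, float] | None = None,
              n_starts: int = 5) -> SeasonalCurve:
    """Fit one year's (or the climatology's) 24 composites with ``method``.

    Requires >= 20 non-missing composites and a seasonal amplitude above
    ``amplitude_floor``; otherwise the pixel is flagged non-seasonal.
    ``init`` optionally seeds the logistic fits with (sos, eos) guesses,
    e.g. from the climatological fit of the same pixel; a well-seeded fit
    needs fewer multi-starts (``n_starts``).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 20:
        return SeasonalCurve(_DOY_GRID, np.full(DAYS_PER_YEAR, np.nan),
                             method, seasonal=False, converged=False)
    t, v = doys[ok], values[ok]
    if v.max() - v.min() < amplitude_floor:
        return SeasonalCurve(_DOY_GRID, np.full(DAYS_PER_YEAR, np.nan),
                             method, seasonal=False, converged=False)

    model_sos = model_eos = None
    if method in ("hants", "polyfit"):
        design = {"hants": _harmonic_design, "polyfit": _poly_design}[method]
        X = design(t)
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        curve = design(_DOY_GRID) @ coef
        resid = X @ coef - v
        converged = True
    elif method == "double_logistic":
        res = _fit_double_logistic(t, v, init=init, n_starts=n_starts)
        if res is None:
            return SeasonalCurve(_DOY_GRID, np.full(DAYS_PER_YEAR, np.nan),
                                 method, seasonal=True, converged=False)
        curve = _double_logistic_model(res.x, _DOY_GRID)
        resid = res.fun
        converged = res.status > 0
        model_sos, model_eos = float(res.x[2]), float(res.x[4])
    else:  # piecewise_logistic
        peak = t[np.argmax(v)]
        rise_mask = t <= peak
        fall_mask = t >= peak
        if rise_mask.sum() < 4 or fall_mask.sum() < 4:
            return SeasonalCurve(_DOY_GRID, np.full(DAYS_PER_YEAR, np.nan),
                                 method, seasonal=True, converged=False)
        s0, e0 = init if init is not None else _slope_scan_init(t, v)
        r1 = _fit_half_sigmoid(t[rise_mask], v[rise_mask], True, s0)
        r2 = _fit_half_sigmoid(t[fall_mask], v[fall_mask], False, e0)
        if r1 is None or r2 is None:
            return SeasonalCurve(_DOY_GRID, np.full(DAYS_PER_YEAR, np.nan),
                                 method, seasonal=True, converged=False)
        curve = np.where(_DOY_GRID <= peak,
                         _sigmoid_half(r1.x, _DOY_GRID, True),
                         _sigmoid_half(r2.x, _DOY_GRID, False))
        resid = np.concatenate([r1.fun, r2.fun])
        converged = r1.status > 0 and r2.status > 0
        model_sos, model_eos = float(r1.x[2]), float(r2.x[2])

    return SeasonalCurve(_DOY_GRID, curve, method, seasonal=True,
                         converged=converged,
                         residual_sd=float(np.std(resid)),
                         model_sos=model_sos, model_eos=model_eos)


# -------------------------------------------------------------- dating ---

def _interior_extreme(inc: np.ndarray, sign: int) -> float:
    """Index of the best interior local extremum of a slope sequence.

    ``sign=+1`` looks for the largest local maximum of ``inc`` (day-to-day
    increase), ``sign=-1`` for the most negative local minimum.  Demanding
    a *local* extremum rejects spurious boundary slopes (polynomial edge
    wiggles steepen toward the domain ends).  Earliest index wins ties;
    NaN when the half-year slope has no interior extremum of that sign.
    """
    s = sign * inc
    if s.size < 3:
        return np.nan
    interior = np.flatnonzero((s[1:-1] >= s[:-2]) & (s[1:-1] >= s[2:])
                              & (s[1:-1] > 0)) + 1
    if interior.size == 0:
        return np.nan
    return float(interior[np.argmax(s[interior])])


def _slope_dates(curve: np.ndarray) -> tuple[float, float]:
    """DOY of max day-to-day increase (first half) / decrease (second half).

    Only interior extrema of the slope count; earliest DOY wins on ties.
    Returns NaN where a half-year has no slope extremum of the right sign
    (monotone or flat halves).
    """
    inc = np.diff(curve)  # inc[d-1] = curve[d+1] - curve[d], d = 1..364
    first = inc[: HALF_YEAR_SPLIT - 1]            # transitions ending <= 182
    second = inc[HALF_YEAR_SPLIT - 1:]
    i = _interior_extreme(first, +1)
    sos = i + 2 if np.isfinite(i) else np.nan     # DOY of arrival day
    j = _interior_extreme(second, -1)
    eos = j + HALF_YEAR_SPLIT + 1 if np.isfinite(j) else np.nan
    return sos, eos


def climatological_dates(curve: SeasonalCurve):
    """Mean-curve transition dates and the NDVI thresholds they define.

    Returns ``(sos_clim, eos_clim, thr_sos, thr_eos)`` (NaNs if undatable).
    For the logistic methods the dates are the model's inflection
    parameters; for hants/polyfit they come from the daily slope scan.
    """
    nan4 = (np.nan,) * 4
    if not curve.seasonal or not np.all(np.isfinite(curve.fitted_ndvi)):
        return nan4
    if curve.model_sos is not None:
        sos = float(_round_half_up(curve.model_sos))
        eos = float(_round_half_up(curve.model_eos))
        if not (1 <= sos < eos <= DAYS_PER_YEAR):
            return nan4
    else:
        sos, eos = _slope_dates(curve.fitted_ndvi)
        if not (np.isfinite(sos) and np.isfinite(eos)):
            return nan4
    thr_sos = float(curve.fitted_ndvi[int(sos) - 1])
    thr_eos = float(curve.fitted_ndvi[int(eos) - 1])
    return sos, eos, thr_sos, thr_eos


def _first_upward_crossing(curve, thr, lo, hi):
    """First DOY in [lo, hi] where the curve crosses thr from below."""
    for d in range(lo, hi):                      # day d -> d+1, 1-based
        a, b = curve[d - 1], curve[d]
        if a <= thr < b and b > a:
            return d + (thr - a) / (b - a)
    return np.nan


def _last_downward_crossing(curve, thr, lo, hi):
    for d in range(hi - 1, lo - 1, -1):
        a, b = curve[d - 1], curve[d]
        if a >= thr > b and b < a:
            return d + (a - thr) / (a - b)
    return np.nan


def annual_dates(year_curve: SeasonalCurve, thr_sos: float, thr_eos: float,
                 eos_search_end: int = DAYS_PER_YEAR):
    """Threshold-crossing dates for one year.

    SOS is the first upward crossing of ``thr_sos`` within DOY 1-182 and
    EOS the last downward crossing of ``thr_eos`` within DOY
    183-``eos_search_end``, linearly interpolated between daily grid
    points and rounded to the nearest integer DOY.  Either date is missing
    when no crossing exists; both are dropped if they fail sos < eos.
    """
    if not year_curve.seasonal or not np.isfinite(thr_sos):
        return np.nan, np.nan
    c = year_curve.fitted_ndvi
    if not np.all(np.isfinite(c)):
        return np.nan, np.nan
    sos = _first_upward_crossing(c, thr_sos, 1, HALF_YEAR_SPLIT)
    # normally EOS lives in the second half year; when a double-season rule
    # truncates the search below mid-year (second season spills into the
    # next year), the first season's own descent is the target instead
    eos_lo = HALF_YEAR_SPLIT + 1 if eos_search_end > HALF_YEAR_SPLIT else 2
    eos = _last_downward_crossing(c, thr_eos, eos_lo,
                                  min(eos_search_end, DAYS_PER_YEAR))
    if np.isfinite(sos):
        sos = float(_round_half_up(sos))
    if np.isfinite(eos):
        eos = float(_round_half_up(eos))
    if np.isfinite(sos) and np.isfinite(eos) and sos >= eos:
        return np.nan, np.nan
    return sos, eos


def resolve_double_season(curve: SeasonalCurve,
                          trough_fraction: float = 0.1) -> dict:
    """Detect a second growing season and decide the EOS search window.

    Bimodality requires two local maxima of the fitted daily curve
    separated by a trough at least ``trough_fraction`` of the curve's
    amplitude below the smaller peak.  With two complete seasons in the
    year, SOS comes from the first season and EOS from the second (the
    default full-year threshold search already yields this).  When the
    second season runs past Dec 31 (curve still high at year end), only
    the first season counts: the EOS search is cut at the trough.
    Unimodal pixels are untouched.
    """
    out = {"bimodal": False, "second_complete": True,
           "eos_search_end": DAYS_PER_YEAR}
    c = curve.fitted_ndvi
    if not curve.seasonal or not np.all(np.isfinite(c)):
        return out
    amp = c.max() - c.min()
    if amp <= 0:
        return out
    interior = np.flatnonzero((c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:])) + 1
    peaks = [i for i in interior]
    # keep prominent peaks only
    peaks = [i for i in peaks if c[i] >= c.min() + 0.2 * amp]
    if len(peaks) < 2:
        return out
    p1, p2 = peaks[0], peaks[-1]
    trough = int(p1 + np.argmin(c[p1:p2 + 1]))
    depth = min(c[p1], c[p2]) - c[trough]
    if depth < trough_fraction * amp:
        return out
    out["bimodal"] = True
    # second season complete if the curve falls back toward the trough
    # level before the year ends
    if c[-1] > c[trough] + 0.5 * (c[p2] - c[trough]):
        out["second_complete"] = False
        out["eos_search_end"] = trough + 1      # 1-based DOY of the trough
    return out


# ------------------------------------------------------------ ensemble ---

def ensemble_phenology(grids: dict[str, PhenologyGrid],
                       min_methods: int = 2) -> PhenologyGrid:
    """Arithmetic mean of per-method SOS/EOS dates, rounded to integer DOY.

    A pixel-year needs at least ``min_methods`` methods with valid dates;
    pixel-years where the averaged dates violate sos < eos are dropped.
    """
    if not grids:
        raise ValueError("no method grids supplied")
    ref = next(iter(grids.values()))
    sos_stack = np.stack([g.sos for g in grids.values()])
    eos_stack = np.stack([g.eos for g in grids.values()])
    n_sos = np.isfinite(sos_stack).sum(axis=0)
    n_eos = np.isfinite(eos_stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        sos = _round_half_up(np.nanmean(sos_stack, axis=0))
        eos = _round_half_up(np.nanmean(eos_stack, axis=0))
    sos[n_sos < min_methods] = np.nan
    eos[n_eos < min_methods] = np.nan
    bad = np.isfinite(sos) & np.isfinite(eos) & (sos >= eos)
    sos[bad] = np.nan
    eos[bad] = np.nan
    return PhenologyGrid(sos=sos, eos=eos, years=ref.years,
                         lat_axis=ref.lat_axis, lon_axis=ref.lon_axis,
                         method="ensemble")


# ------------------------------------------------------- grid extraction ---

def _dates_from_daily_curves(clim_curve, year_curves, method):
    """Date all years of one pixel given precomputed daily curves."""
    sc = SeasonalCurve(_DOY_GRID, clim_curve, method)
    _, _, thr_sos, thr_eos = climatological_dates(sc)
    ny = year_curves.shape[0]
    sos = np.full(ny, np.nan)
    eos = np.full(ny, np.nan)
    if not np.isfinite(thr_sos):
        return sos, eos
    for j in range(ny):
        yc = SeasonalCurve(_DOY_GRID, year_curves[j], method)
        rule = resolve_double_season(yc)
        sos[j], eos[j] = annual_dates(yc, thr_sos, thr_eos,
                                      rule["eos_search_end"])
    return sos, eos


def extract_phenology(cube: NdviCube,
                      methods=METHODS,
                      amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
                      min_methods: int = 2) -> dict[str, PhenologyGrid]:
    """Run the full extraction on a gridded NDVI cube.

    Per pixel and method: fit the multi-year mean composites, derive the
    climatological transition dates and NDVI thresholds, then date each
    year's own fitted curve by threshold crossing.  Returns one
    PhenologyGrid per method plus the cross-method ``"ensemble"``.
    """
    ny, nc, nlat, nlon = cube.values.shape
    doys = cube.composite_midpoint_doy
    out: dict[str, PhenologyGrid] = {}

    # fast path for the two linear methods: one projector serves all
    projectors = {m: linear_method_projector(doys, m)
                  for m in methods if m in ("hants", "polyfit")}

    for method in methods:
        sos = np.full((ny, nlat, nlon), np.nan)
        eos = np.full((ny, nlat, nlon), np.nan)
        for iy in range(nlat):
            for ix in range(nlon):
                comps = cube.values[:, :, iy, ix]      # (ny, 24)
                clim = np.nanmean(comps, axis=0)
                if (not np.all(np.isfinite(clim))
                        or clim.max() - clim.min() < amplitude_floor):
                    continue
                if method in projectors and np.all(np.isfinite(comps)):
                    P = projectors[method]
                    clim_curve = P @ clim
                    year_curves = comps @ P.T
                    s, e = _dates_from_daily_curves(
                        clim_curve, year_curves, method)
                else:
                    cc = fit_curve(doys, clim, method, amplitude_floor)
                    sc, ec, thr_s, thr_e = climatological_dates(cc)
                    if not np.isfinite(thr_s):
                        continue
                    s = np.full(ny, np.nan)
                    e = np.full(ny, np.nan)
                    init = ((cc.model_sos, cc.model_eos)
                            if cc.model_sos is not None else (sc, ec))
                    for j in range(ny):
                        # seeded from the climatological fit: 2 starts
                        yc = fit_curve(doys, comps[j], method,
                                       amplitude_floor, init=init,
                                       n_starts=2)
                        rule = resolve_double_season(yc)
                        s[j], e[j] = annual_dates(
                            yc, thr_s, thr_e, rule["eos_search_end"])
                sos[:, iy, ix] = s
                eos[:, iy, ix] = e
        bad = np.isfinite(sos) & np.isfinite(eos) & (sos >= eos)
        sos[bad] = np.nan
        eos[bad] = np.nan
        out[method] = PhenologyGrid(sos=sos, eos=eos, years=cube.years,
                                    lat_axis=cube.lat_axis,
                                    lon_axis=cube.lon_axis, method=method)
    out["ensemble"] = ensemble_phenology(
        {m: g for m, g in out.items()}, min_methods=min_methods)
    return out
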