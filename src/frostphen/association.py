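"""Spatial association between changes in phenology, temperature and GSFD.

Local structure is measured with first-order partial correlations inside
2.5 x 2.5 degree moving windows (5 x 5 pixels on a 0.5 degree grid,
centered on every output cell, truncated at the edges): the correlation of
the GSFD change with the growing-season-length change controlling for the
T_min change, and vice versa.  Continental-scale structure is summarized
by a 1-day binned 2-D change density with quadrant percentages and by the
area-weighted regression slope of the GSFD change on the GSL change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "partial_correlation",
    "PartialCorrMap",
    "moving_window_partial",
    "binned_change_density",
    "continental_association",
]


def partial_correlation(x, y, z):
    """First-order partial correlation r_xy.z with a two-sided p-value.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the
    p-value comes from the t transform on n - 3 degrees of freedom.
    Incomplete triples are dropped; returns (nan, nan) for fewer than 4
    complete triples or when a control correlation is +-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    n = int(ok.sum())
    if n < 4:
        return np.nan, np.nan
    x, y, z = x[ok], y[ok], z[ok]
    if np.std(x) == 0 or np.std(y) == 0 or np.std(z) == 0:
        return np.nan, np.nan
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = (1 - rxz ** 2) * (1 - ryz ** 2)
    if denom <= 1e-12:          # a control correlation of (numerically) +-1
        return np.nan, np.nan
    r = (rxy - rxz * ryz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class PartialCorrMap:
    """Moving-window partial correlations per output cell."""

    r_phen: np.ndarray
    p_phen: np.ndarray
    r_temp: np.ndarray
    p_temp: np.ndarray
    n_eff: np.ndarray
    lat_axis: np.ndarray
    lon_axis: np.ndarray
    window_pixels: int = 5

    def significant_positive_fraction(self, which: str = "phen",
                                      alpha: float = 0.05) -> float:
        r = self.r_phen if which == "phen" else self.r_temp
        p = self.p_phen if which == "phen" else self.p_temp
        valid = np.isfinite(r)
        if not valid.any():
            return np.nan
        return float(((r > 0) & (p < alpha) & valid).sum() / valid.sum())


def moving_window_partial(delta_gsfd, delta_gsl, delta_tmin,
                          lat_axis, lon_axis,
                          window_pixels: int = 5,
                          min_pixels: int = 10) -> PartialCorrMap:
    """Windowed partial correlations of the three change maps.

    For every output cell, all valid pixels of the ``window_pixels`` x
    ``window_pixels`` neighborhood (2.5 degrees at 0.5 degree resolution;
    truncated at grid edges) enter two partial correlations: GSFD~GSL
    controlling T_min (``r_phen``) and GSFD~T_min controlling GSL
    (``r_temp``).  Cells with fewer than ``min_pixels`` valid pixels are
    missing.
    """
    fd = np.asarray(delta_gsfd, dtype=float)
    gl = np.asarray(delta_gsl, dtype=float)
    tm = np.asarray(delta_tmin, dtype=float)
    if fd.shape != gl.shape or fd.shape != tm.shape:
        raise ValueError("change maps are not aligned")
    nlat, nlon = fd.shape
    h = window_pixels // 2
    out = {k: np.full((nlat, nlon), np.nan)
           for k in ("r_phen", "p_phen", "r_temp", "p_temp")}
    n_eff = np.zeros((nlat, nlon), dtype=int)
    for i in range(nlat):
        i0, i1 = max(0, i - h), min(nlat, i + h + 1)
        for j in range(nlon):
            j0, j1 = max(0, j - h), min(nlon, j + h + 1)
            wfd = fd[i0:i1, j0:j1].ravel()
            wgl = gl[i0:i1, j0:j1].ravel()
            wtm = tm[i0:i1, j0:j1].ravel()
            ok = np.isfinite(wfd) & np.isfinite(wgl) & np.isfinite(wtm)
            n_eff[i, j] = ok.sum()
            if n_eff[i, j] < min_pixels:
                continue
            out["r_phen"][i, j], out["p_phen"][i, j] = partial_correlation(
                wfd[ok], wgl[ok], wtm[ok])
            out["r_temp"][i, j], out["p_temp"][i, j] = partial_correlation(
                wfd[ok], wtm[ok], wgl[ok])
    return PartialCorrMap(r_phen=out["r_phen"], p_phen=out["p_phen"],
                          r_temp=out["r_temp"], p_temp=out["p_temp"],
                          n_eff=n_eff, lat_axis=np.asarray(lat_axis),
                          lon_axis=np.asarray(lon_axis),
                          window_pixels=window_pixels)


def binned_change_density(delta_phen, delta_fd, bin_days: float = 1.0):
    """1-day binned 2-D density of (phenology change, frost-day change).

    Returns ``(phen_edges, fd_edges, density_pct, quadrants)`` where
    ``density_pct`` is the percentage of valid pixels per bin and
    ``quadrants`` maps '+{+,-}' style keys (phenology sign then frost
    sign; zero counts as the non-positive side) to percentages summing
    to 100.
    """
    dp = np.asarray(delta_phen, dtype=float).ravel()
    df = np.asarray(delta_fd, dtype=float).ravel()
    ok = np.isfinite(dp) & np.isfinite(df)
    if not ok.any():
        raise ValueError("no valid pixel pairs")
    dp, df = dp[ok], df[ok]

    def edges(v):
        lo = np.floor(v.min() / bin_days) * bin_days
        hi = np.ceil(v.max() / bin_days) * bin_days + bin_days
        return np.arange(lo, hi + 0.5 * bin_days, bin_days)

    H, pe, fe = np.histogram2d(dp, df, bins=[edges(dp), edges(df)])
    density = 100.0 * H / dp.size
    quadrants = {
        "++": 100.0 * np.mean((dp > 0) & (df > 0)),
        "+-": 100.0 * np.mean((dp > 0) & (df <= 0)),
        "-+": 100.0 * np.mean((dp <= 0) & (df > 0)),
        "--": 100.0 * np.mean((dp <= 0) & (df <= 0)),
    }
    return pe, fe, density, quadrants


def continental_association(delta_gsl, delta_fd, lat_axis,
                            min_pixels: int = 30):
    """Area-weighted slope of the frost-day change on the GSL change.

    Weighted least squares with cos(latitude) weights; returns
    ``(slope, intercept, t, p, n)`` with a two-sided test of slope != 0,
    or NaNs when the GSL change has (weighted) zero variance.
    """
    gl = np.asarray(delta_gsl, dtype=float)
    fd = np.asarray(delta_fd, dtype=float)
    w2d = np.broadcast_to(np.cos(np.deg2rad(np.asarray(lat_axis)))[:, None],
                          gl.shape)
    ok = np.isfinite(gl) & np.isfinite(fd)
    n = int(ok.sum())
    if n < min_pixels:
        raise ValueError(f"need >= {min_pixels} valid pixels, got {n}")
    x, y, w = gl[ok], fd[ok], w2d[ok]
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = np.average((x - xbar) ** 2, weights=w)
    if sxx <= 0:
        return np.nan, np.nan, np.nan, np.nan, n
    sxy = np.average((x - xbar) * (y - ybar), weights=w)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    # weighted residual variance with n-2 dof, normalized weights
    wsum = w.sum()
    s2 = np.sum(w * resid ** 2) / wsum * n / (n - 2)
    se = np.sqrt(s2 / (sxx * n))
    with np.errstate(divide="ignore"):
        t = slope / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(slope), float(intercept), float(t), float(p), n
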