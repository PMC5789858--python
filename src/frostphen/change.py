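"""Decadal change maps: means, Welch difference tests, area statistics.

Decade windows default to 1982-1989 / 1990-1999 / 2000-2009 (the record
starts in 1982 and the in-situ comparison ends in 2009) and are fully
configurable.  Hemispheric area fractions weight pixels by cos(latitude).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import ChangeMap

__all__ = [
    "DEFAULT_DECADES",
    "decadal_mean",
    "difference_test",
    "area_fraction",
    "region_mean_change",
]

DEFAULT_DECADES = {
    "1980s": range(1982, 1990),
    "1990s": range(1990, 2000),
    "2000s": range(2000, 2010),
}


def _select_years(values: np.ndarray, years: np.ndarray, decade) -> np.ndarray:
    mask = np.isin(years, np.asarray(list(decade)))
    if not mask.any():
        raise ValueError("decade contains no years of the record")
    return values[mask]


def decadal_mean(values: np.ndarray, years: np.ndarray, decade,
                 min_years: int = 7) -> np.ndarray:
    """Arithmetic mean of an annual metric over a decade, per pixel.

    Pixels with fewer than ``min_years`` valid years are missing.
    """
    sel = _select_years(values, years, decade)
    n = np.isfinite(sel).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(sel, axis=0)
    mean = np.asarray(mean, dtype=float)
    mean[n < min_years] = np.nan
    return mean


def welch_test(a: np.ndarray, b: np.ndarray):
    """Vectorized two-sided Welch t-test along axis 0, NaN-aware.

    Returns (delta, p).  Zero variance in both samples: equal means give
    p = 1 (no evidence of change), unequal means give p = 0 (a change is
    certain under the observed data) by convention.
    """
    na = np.isfinite(a).sum(axis=0).astype(float)
    nb = np.isfinite(b).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(a, axis=0)
        mb = np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1)
        vb = np.nanvar(b, axis=0, ddof=1)
        delta = mb - ma
        se2 = va / na + vb / nb
        t = delta / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (va == 0) & (vb == 0)
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), 0.0, p)
    invalid = (na < 3) | (nb < 3) | ~np.isfinite(delta)
    delta = np.where(invalid, np.nan, delta)
    p = np.where(invalid, np.nan, p)
    return delta, p


def difference_test(values: np.ndarray, years: np.ndarray,
                    decade_a, decade_b, lat_axis, lon_axis,
                    alpha: float = 0.05) -> ChangeMap:
    """Per-pixel Welch test of decade_b minus decade_a annual values."""
    a = _select_years(values, years, decade_a)
    b = _select_years(values, years, decade_b)
    delta, p = welch_test(a, b)
    return ChangeMap(delta=delta, p_value=p, lat_axis=np.asarray(lat_axis),
                     lon_axis=np.asarray(lon_axis), alpha=alpha,
                     n1=len(list(decade_a)), n2=len(list(decade_b)))


def _weights(change: ChangeMap) -> np.ndarray:
    w = np.cos(np.deg2rad(change.lat_axis))[:, None]
    return np.broadcast_to(w, change.delta.shape)


def area_fraction(change: ChangeMap, direction: str = "increase",
                  require_significance: bool = True) -> float:
    """Cos-latitude-weighted fraction of valid pixels changing one way."""
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    valid = np.isfinite(change.delta)
    if not valid.any():
        raise ValueError("change map has no valid pixels")
    sign = change.delta > 0 if direction == "increase" else change.delta < 0
    pick = valid & sign
    if require_significance:
        pick &= change.significant
    w = _weights(change)
    return float(w[pick].sum() / w[valid].sum())


def region_mean_change(change: ChangeMap, mask: np.ndarray,
                       min_pixels: int = 10):
    """Area-weighted mean +- sd of pixel deltas in a region, with a
    one-sample t-test of the deltas against zero.

    Returns ``(mean, sd, t, p, n)``.
    """
    mask = np.asarray(mask, dtype=bool)
    valid = mask & np.isfinite(change.delta)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("region mask selects no valid pixels")
    if n < min_pixels:
        raise ValueError(f"region has only {n} valid pixels (< {min_pixels})")
    d = change.delta[valid]
    w = _weights(change)[valid]
    mean = float(np.average(d, weights=w))
    sd = float(np.sqrt(np.average((d - mean) ** 2, weights=w)))
    t, p = stats.ttest_1samp(d, 0.0)
    return mean, sd, float(t), float(p), n
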