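"""Site-level (PEP725-style) phenology filtering and frost counting.

Sites report leaf unfolding and leaf senescence as day-of-year.  Records
with unfolding after the end of June (DOY 181) or senescence before the
beginning of July (DOY 182) are treated as outliers and dropped; analysis
sets keep sites with a minimum number of observation years inside the
study period.  Frost counts use the site's [unfold, senesce] window with
the daily minimum temperature of the containing grid cell, and decadal
changes are compared pairwise with the satellite-window counts at the
same cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DAYS_PER_YEAR, DailyTminGrid, SOLSTICE_DOY
from .frost import FROST_THRESHOLD_C

__all__ = ["filter_sites", "site_frost_counts", "compare_decadal"]

#: "End of June" in the fixed 365-day calendar.
END_OF_JUNE_DOY = 181
#: "Beginning of July".
BEGIN_OF_JULY_DOY = 182


def filter_sites(records: pd.DataFrame, start_year: int = 1982,
                 end_year: int = 2009, min_years: int = 28):
    """Apply the outlier and completeness filters to a site table.

    Site-years with unfolding later than DOY 181 or senescence earlier
    than DOY 182 are removed; the remaining records are restricted to
    [start_year, end_year].  Returns ``(clean, sets)`` where ``sets``
    holds the site-id lists with at least ``min_years`` years of
    unfolding, of senescence, and of both.
    """
    df = records.copy()
    df = df[(df["year"] >= start_year) & (df["year"] <= end_year)]
    bad_unfold = df["unfold_doy"].notna() & (df["unfold_doy"] > END_OF_JUNE_DOY)
    bad_senesce = (df["senesce_doy"].notna()
                   & (df["senesce_doy"] < BEGIN_OF_JULY_DOY))
    df = df[~(bad_unfold | bad_senesce)]

    def sites_with(mask):
        counts = df[mask].groupby("site_id")["year"].nunique()
        return sorted(counts[counts >= min_years].index)

    sets = {
        "unfolding": sites_with(df["unfold_doy"].notna()),
        "senescence": sites_with(df["senesce_doy"].notna()),
        "both": sites_with(df["unfold_doy"].notna()
                           & df["senesce_doy"].notna()),
    }
    return df.reset_index(drop=True), sets


def _containing_cell(lat, lon, lat_axis, lon_axis):
    """Index of the grid cell whose center is nearest (containing cell on
    a uniform cell-center grid)."""
    iy = int(np.argmin(np.abs(lat_axis - lat)))
    ix = int(np.argmin(np.abs(lon_axis - lon)))
    res_lat = np.abs(np.diff(lat_axis)).max() if lat_axis.size > 1 else np.inf
    res_lon = np.abs(np.diff(lon_axis)).max() if lon_axis.size > 1 else np.inf
    if (abs(lat_axis[iy] - lat) > res_lat / 2 + 1e-9
            or abs(lon_axis[ix] - lon) > res_lon / 2 + 1e-9):
        return None
    return iy, ix


def site_frost_counts(sites: pd.DataFrame,
                      daily: DailyTminGrid) -> pd.DataFrame:
    """Frost counts per site-year inside the observed [unfold, senesce].

    Each site is matched to its containing grid cell; sites outside the
    grid are skipped (reported in the ``skipped`` attribute of the
    result).  Counts use the solstice split.  Site-years with a missing
    date yield missing counts.
    """
    rows = []
    skipped = []
    year_index = {int(y): j for j, y in enumerate(daily.years)}
    for (sid, lat, lon), group in sites.groupby(["site_id", "lat", "lon"]):
        cell = _containing_cell(lat, lon, daily.lat_axis, daily.lon_axis)
        if cell is None:
            skipped.append(sid)
            continue
        iy, ix = cell
        for _, rec in group.iterrows():
            year = int(rec["year"])
            if year not in year_index:
                continue
            unfold, senesce = rec["unfold_doy"], rec["senesce_doy"]
            if pd.isna(unfold) or pd.isna(senesce) or unfold >= senesce:
                rows.append((sid, year, np.nan, np.nan, np.nan, iy, ix))
                continue
            s, e = int(unfold), min(int(senesce), DAYS_PER_YEAR)
            tm = daily.values[year_index[year], :, iy, ix]
            frost = tm < FROST_THRESHOLD_C
            cut = min(SOLSTICE_DOY, e)
            spr = int(frost[s - 1:cut].sum()) if s <= cut else 0
            fal = int(frost[max(cut, s - 1):e].sum())
            rows.append((sid, year, spr + fal, spr, fal, iy, ix))
    out = pd.DataFrame(rows, columns=["site_id", "year", "gsfd", "spr_fd",
                                      "fal_fd", "cell_iy", "cell_ix"])
    out.attrs["skipped"] = skipped
    return out


def compare_decadal(site_counts: pd.DataFrame, satellite_counts: np.ndarray,
                    years: np.ndarray, decade_a, decade_b,
                    metric: str = "gsfd", min_pairs: int = 10):
    """Paired decadal change: in-situ windows vs satellite windows.

    For every site, the decadal delta of its in-situ count is paired with
    the delta of the satellite-window count at its grid cell.  Returns a
    dict with the paired deltas, their means, the mean paired difference,
    and the fraction of pairs whose deltas agree in sign.
    """
    years = np.asarray(years)
    in_a = np.isin(years, np.asarray(list(decade_a)))
    in_b = np.isin(years, np.asarray(list(decade_b)))
    pairs = []
    for sid, group in site_counts.groupby("site_id"):
        g = group.set_index("year")[metric]
        iy = int(group["cell_iy"].iloc[0])
        ix = int(group["cell_ix"].iloc[0])
        site_a = g.reindex(years[in_a]).to_numpy(dtype=float)
        site_b = g.reindex(years[in_b]).to_numpy(dtype=float)
        if np.isfinite(site_a).sum() < 3 or np.isfinite(site_b).sum() < 3:
            continue
        d_site = np.nanmean(site_b) - np.nanmean(site_a)
        sat = satellite_counts[:, iy, ix]
        sat_a, sat_b = sat[in_a], sat[in_b]
        if np.isfinite(sat_a).sum() < 3 or np.isfinite(sat_b).sum() < 3:
            continue
        d_sat = np.nanmean(sat_b) - np.nanmean(sat_a)
        pairs.append((sid, d_site, d_sat))
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} matched site-cell pairs "
                         f"(need >= {min_pairs})")
    df = pd.DataFrame(pairs, columns=["site_id", "delta_site", "delta_sat"])
    same_sign = np.sign(df["delta_site"]) == np.sign(df["delta_sat"])
    nonzero = (df["delta_site"] != 0) & (df["delta_sat"] != 0)
    return {
        "pairs": df,
        "mean_delta_site": float(df["delta_site"].mean()),
        "sd_delta_site": float(df["delta_site"].std(ddof=1)),
        "mean_delta_sat": float(df["delta_sat"].mean()),
        "mean_paired_difference": float(
            (df["delta_site"] - df["delta_sat"]).mean()),
        "sign_agreement": float(same_sign[nonzero].mean())
        if nonzero.any() else np.nan,
        "n_pairs": len(df),
    }
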