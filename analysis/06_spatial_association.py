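#!/usr/bin/env python
"""Test whether longer growing seasons go with more frost exposure.

Builds the decadal change maps of GSFD, growing-season length, and
growing-season mean T_min, then (a) computes 2.5 x 2.5 degree
moving-window partial correlations of the GSFD change with each driver
controlling for the other, and (b) fits the continental area-weighted
slope of the GSFD change on the GSL change with a 1-day binned density.
"""

import csv
from pathlib import Path

import numpy as np

from frostphen import association, change, frost, grid_io

OUT = Path("results/analysis")
DEC_A = range(1982, 1990)
DEC_B = range(2000, 2010)


def main():
    tmin = grid_io.read_tmin(OUT / "tmin.nc")
    ens = grid_io.read_phenology(OUT / "phenology_ensemble.nc")
    counts = grid_io.read_frost_counts(OUT / "frost_counts.nc")
    daily = frost.daily_min(tmin)
    args = (ens.years, DEC_A, DEC_B, ens.lat_axis, ens.lon_axis)

    d_fd = change.difference_test(counts.gsfd, *args).delta
    d_gsl = change.difference_test(ens.gsl, *args).delta
    doy = np.arange(1, 366)[None, :, None, None]
    in_season = (doy >= ens.sos[:, None]) & (doy <= ens.eos[:, None])
    gs_mean = np.nanmean(np.where(in_season, daily.values, np.nan), axis=1)
    d_tmin = change.difference_test(gs_mean, *args).delta
    print(f"growing-season T_min change (pixel mean): "
          f"{np.nanmean(d_tmin):+.2f} degC")

    pcm = association.moving_window_partial(d_fd, d_gsl, d_tmin,
                                            ens.lat_axis, ens.lon_axis)
    fp = pcm.significant_positive_fraction("phen")
    ft = pcm.significant_positive_fraction("temp")
    print(f"windows with significant positive partial correlation: "
          f"GSFD~GSL {fp:.0%} vs GSFD~T_min {ft:.0%}")

    slope, intercept, t, p, n = association.continental_association(
        d_gsl, d_fd, ens.lat_axis)
    print(f"continental slope: {slope:+.3f} frost days per GSL day "
          f"(p = {p:.2g}, n = {n})")

    pe, fe, density, quad = association.binned_change_density(d_gsl, d_fd)
    print("quadrant shares (dGSL sign x dGSFD sign):",
          {k: f"{v:.0f}%" for k, v in quad.items()})

    with open(OUT / "partial_correlations.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lat", "lon", "r_phen", "p_phen", "r_temp", "p_temp",
                    "n_eff"])
        for i, lat in enumerate(ens.lat_axis):
            for j, lon in enumerate(ens.lon_axis):
                w.writerow([lat, lon, pcm.r_phen[i, j], pcm.p_phen[i, j],
                            pcm.r_temp[i, j], pcm.p_temp[i, j],
                            pcm.n_eff[i, j]])
    np.savetxt(OUT / "change_density.csv", density, delimiter=",")
    print(f"wrote partial_correlations.csv, change_density.csv -> {OUT}")


if __name__ == "__main__":
    main()
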