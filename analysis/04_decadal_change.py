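#!/usr/bin/env python
"""Decadal change in frost counts with per-pixel significance.

Welch-tests the annual GSFD/SPR-FD/FAL-FD fields between decade pairs
(1980s vs 1990s, 1990s vs 2000s, 1980s vs 2000s), writes the change maps,
and tabulates cos-latitude-weighted area fractions of significant
increase/decrease per metric and decade pair.
"""

import csv
from pathlib import Path

import numpy as np

from frostphen import change, grid_io

OUT = Path("results/analysis")

DECADES = {"1980s": range(1982, 1990), "1990s": range(1990, 2000),
           "2000s": range(2000, 2010)}
PAIRS = [("1980s", "1990s"), ("1990s", "2000s"), ("1980s", "2000s")]


def main():
    counts = grid_io.read_frost_counts(OUT / "frost_counts.nc")
    metrics = {"gsfd": counts.gsfd, "spr_fd": counts.spr_fd,
               "fal_fd": counts.fal_fd}
    rows = []
    for a, b in PAIRS:
        for name, metric in metrics.items():
            cm = change.difference_test(metric, counts.years, DECADES[a],
                                        DECADES[b], counts.lat_axis,
                                        counts.lon_axis)
            grid_io.write_change_map(cm, OUT / f"change_{name}_{a}_{b}.nc")
            inc = change.area_fraction(cm, "increase")
            dec = change.area_fraction(cm, "decrease")
            rows.append((f"{a}->{b}", name, np.nanmean(cm.delta),
                         100 * inc, 100 * dec))
    with open(OUT / "area_fractions.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["decades", "metric", "mean_delta_days",
                    "sig_increase_pct", "sig_decrease_pct"])
        w.writerows(rows)
    print("decades        metric   mean d   sig+ %   sig- %")
    for r in rows:
        print(f"{r[0]:14s} {r[1]:8s} {r[2]:+7.2f} {r[3]:8.1f} {r[4]:8.1f}")
    print(f"wrote change_<metric>_<decades>.nc, area_fractions.csv -> {OUT}")


if __name__ == "__main__":
    main()
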