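"""Site-level phenology filters, frost counts, and the paired decadal
comparison against satellite windows."""

import numpy as np
import pandas as pd
import pytest

from frostphen import frost, insitu, synthetic
from frostphen.containers import DailyTminGrid, PhenologyGrid

YEARS = np.arange(1982, 2010)


def pinned(**over):
    base = {
        "sos0": 120.0, "eos0": 280.0, "sos_trend": 0.0, "eos_trend": 0.0,
        "ndvi_winter": 0.1, "ndvi_amplitude": 0.5,
        "tmin_annual_mean": 4.0, "tmin_seasonal_amplitude": 14.0,
        "tmin_diurnal_amplitude": 4.0, "tmin_trend": 0.0,
        "tmin_ar1": 0.7, "tmin_noise_sd": 3.0,
    }
    base.update(over)
    return {k: (v, v) if np.isscalar(v) else v for k, v in base.items()}


def site_row(site_id, year, unfold, senesce, lat=50.0, lon=0.0):
    return {"site_id": site_id, "lat": lat, "lon": lon, "year": year,
            "unfold_doy": unfold, "senesce_doy": senesce}


class TestFilterSites:
    def test_late_unfolding_site_year_dropped(self):
        tab = pd.DataFrame([site_row("a", 1990, 200, 280),
                            site_row("a", 1991, 120, 280)])
        clean, _ = insitu.filter_sites(tab, min_years=1)
        assert list(clean["year"]) == [1991]

    def test_early_senescence_dropped(self):
        tab = pd.DataFrame([site_row("a", 1990, 120, 170)])
        clean, _ = insitu.filter_sites(tab, min_years=1)
        assert clean.empty

    def test_complete_site_in_all_three_sets(self):
        rows = [site_row("a", y, 120, 280) for y in range(1982, 2010)]
        tab = pd.DataFrame(rows)
        _, sets = insitu.filter_sites(tab, min_years=28)
        assert sets == {"unfolding": ["a"], "senescence": ["a"],
                        "both": ["a"]}

    def test_set_sizes_match_direct_count(self):
        truth = synthetic.gen_truth(3, 4, seed=2)
        tab = synthetic.gen_insitu(truth, 40, YEARS, obs_noise_sd=2.0,
                                   missing_rate=0.3, seed=3)
        min_years = 20
        clean, sets = insitu.filter_sites(tab, min_years=min_years)
        # direct oracle on the cleaned table
        for key, col in (("unfolding", "unfold_doy"),
                         ("senescence", "senesce_doy")):
            counts = clean[clean[col].notna()].groupby("site_id")[
                "year"].nunique()
            assert sets[key] == sorted(counts[counts >= min_years].index)


class TestSiteFrostCounts:
    def _daily(self, frost_doys, ny=1):
        v = np.full((ny, 365, 2, 2), 5.0)
        for d in frost_doys:
            v[:, d - 1] = -1.0
        return DailyTminGrid(values=v, years=np.arange(2000, 2000 + ny),
                             lat_axis=[50.0, 49.5], lon_axis=[0.0, 0.5])

    def test_single_spring_frost_day(self):
        daily = self._daily([155])
        tab = pd.DataFrame([site_row("a", 2000, 150, 250)])
        out = insitu.site_frost_counts(tab, daily)
        rec = out.iloc[0]
        assert (rec["gsfd"], rec["spr_fd"], rec["fal_fd"]) == (1, 1, 0)

    def test_missing_senescence_gives_missing_count(self):
        daily = self._daily([155])
        tab = pd.DataFrame([site_row("a", 2000, 150, np.nan)])
        out = insitu.site_frost_counts(tab, daily)
        assert np.isnan(out.iloc[0]["gsfd"])

    def test_site_outside_grid_skipped(self):
        daily = self._daily([155])
        tab = pd.DataFrame([site_row("far", 2000, 150, 250, lat=20.0)])
        out = insitu.site_frost_counts(tab, daily)
        assert out.empty
        assert out.attrs["skipped"] == ["far"]

    def test_counts_match_per_site_brute_force(self):
        truth = synthetic.gen_truth(4, 5, seed=4)
        tmin = synthetic.gen_tmin(truth, YEARS[:6], timestep_hours=6, seed=5)
        daily = frost.daily_min(tmin)
        tab = synthetic.gen_insitu(truth, 30, YEARS[:6], obs_noise_sd=3.0,
                                   missing_rate=0.1, seed=6)
        out = insitu.site_frost_counts(tab, daily)
        merged = out.merge(tab, on=["site_id", "year"])
        year_idx = {int(y): j for j, y in enumerate(daily.years)}
        for _, r in merged.iterrows():
            series = daily.values[year_idx[r["year"]], :,
                                  int(r["cell_iy"]), int(r["cell_ix"])]
            s, e = int(r["unfold_doy"]), int(r["senesce_doy"])
            expected = sum(1 for d in range(s, e + 1) if series[d - 1] < 0)
            assert r["gsfd"] == expected

    def test_window_containment_bounds_satellite_count(self):
        """Site gsfd <= cell gsfd whenever the site window is inside."""
        truth = synthetic.gen_truth(3, 3, pinned(), seed=7)
        tmin = synthetic.gen_tmin(truth, YEARS[:4], timestep_hours=6, seed=8)
        daily = frost.daily_min(tmin)
        phen = PhenologyGrid(
            sos=np.full((4, 3, 3), 110.0), eos=np.full((4, 3, 3), 290.0),
            years=YEARS[:4], lat_axis=truth.lat_axis,
            lon_axis=truth.lon_axis)
        cell = frost.count_grid(daily, phen).gsfd
        tab = pd.DataFrame([site_row("a", int(y), 130, 270,
                                     lat=truth.lat_axis[1],
                                     lon=truth.lon_axis[1])
                            for y in YEARS[:4]])
        out = insitu.site_frost_counts(tab, daily)
        for _, r in out.iterrows():
            j = int(r["year"] - YEARS[0])
            assert r["gsfd"] <= cell[j, 1, 1]

    def test_identical_windows_identical_counts(self):
        truth = synthetic.gen_truth(2, 2, pinned(), seed=9)
        tmin = synthetic.gen_tmin(truth, YEARS[:3], timestep_hours=6, seed=9)
        daily = frost.daily_min(tmin)
        phen = PhenologyGrid(
            sos=np.full((3, 2, 2), 120.0), eos=np.full((3, 2, 2), 280.0),
            years=YEARS[:3], lat_axis=truth.lat_axis, lon_axis=truth.lon_axis)
        cell = frost.count_grid(daily, phen).gsfd
        tab = pd.DataFrame([site_row("a", int(y), 120, 280,
                                     lat=truth.lat_axis[0],
                                     lon=truth.lon_axis[0])
                            for y in YEARS[:3]])
        out = insitu.site_frost_counts(tab, daily).set_index("year")
        for y in YEARS[:3]:
            assert out.loc[int(y), "gsfd"] == cell[int(y - YEARS[0]), 0, 0]


class TestCompareDecadal:
    def test_shared_temperature_trend_aligns_delta_signs(self):
        """Cooling trend shared by both sources: decadal deltas agree in
        sign for nearly all pairs."""
        truth = synthetic.gen_truth(4, 5, pinned(
            tmin_trend=(-0.12, -0.08), tmin_noise_sd=(1.0, 2.0)), seed=10)
        tmin = synthetic.gen_tmin(truth, YEARS, timestep_hours=6, seed=11)
        daily = frost.daily_min(tmin)
        ny = YEARS.size
        phen = PhenologyGrid(
            sos=np.full((ny, 4, 5), 110.0), eos=np.full((ny, 4, 5), 290.0),
            years=YEARS, lat_axis=truth.lat_axis, lon_axis=truth.lon_axis)
        sat = frost.count_grid(daily, phen).gsfd
        tab = synthetic.gen_insitu(truth, 30, YEARS, obs_noise_sd=0.0,
                                   missing_rate=0.0, seed=12)
        # site windows strictly inside the satellite ones
        tab["unfold_doy"] = 130
        tab["senesce_doy"] = 270
        counts = insitu.site_frost_counts(tab, daily)
        res = insitu.compare_decadal(counts, sat, YEARS,
                                     range(1982, 1990), range(2000, 2010))
        assert res["n_pairs"] >= 10
        assert res["sign_agreement"] >= 0.9
        assert res["mean_delta_site"] > 0          # cooling adds frost days

    def test_too_few_pairs_rejected(self):
        counts = pd.DataFrame({"site_id": ["a"], "year": [1985],
                               "gsfd": [1.0], "spr_fd": [1.0],
                               "fal_fd": [0.0], "cell_iy": [0],
                               "cell_ix": [0]})
        sat = np.zeros((len(YEARS), 1, 1))
        with pytest.raises(ValueError, match="pairs"):
            insitu.compare_decadal(counts, sat, YEARS,
                                   range(1982, 1990), range(2000, 2010))
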