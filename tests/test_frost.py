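"""Frost counting: oracle equivalence, the spring/autumn partition, and
strict threshold semantics."""

import numpy as np
import pytest

from frostphen import frost, synthetic
from frostphen.containers import (
    DAYS_PER_YEAR,
    SOLSTICE_DOY,
    DailyTminGrid,
    PhenologyGrid,
    TminCube,
)

YEARS = np.arange(2000, 2003)


def make_daily(values):
    """DailyTminGrid from a (ny, 365, nlat, nlon) array."""
    v = np.asarray(values, dtype=float)
    return DailyTminGrid(values=v, years=np.arange(2000, 2000 + v.shape[0]),
                         lat_axis=50.0 - 0.5 * np.arange(v.shape[2]),
                         lon_axis=0.5 * np.arange(v.shape[3]))


def day_loop_gsfd(daily_series, start, end):
    """Scalar day-by-day oracle for one pixel-year window."""
    n = 0
    for d in range(start, end + 1):
        if daily_series[d - 1] < 0.0:
            n += 1
    return n


class TestDailyMin:
    def test_constant_cube(self):
        truth = synthetic.gen_truth(2, 2, {
            k: (v, v) for k, v in {
                "sos0": 120, "eos0": 280, "sos_trend": 0, "eos_trend": 0,
                "ndvi_winter": 0.1, "ndvi_amplitude": 0.5,
                "tmin_annual_mean": 5.0, "tmin_seasonal_amplitude": 0.0,
                "tmin_diurnal_amplitude": 0.0, "tmin_trend": 0.0,
                "tmin_ar1": 0.0, "tmin_noise_sd": 0.0}.items()}, seed=0)
        cube = synthetic.gen_tmin(truth, YEARS, timestep_hours=6, seed=0)
        daily = frost.daily_min(cube)
        np.testing.assert_allclose(daily.values, 5.0)

    def test_single_day_sample_min(self):
        vals = np.array([2, 1, -3, 0, 4, 6, 5, 3], dtype=float)
        v = np.full((DAYS_PER_YEAR * 8, 1, 1), 10.0)
        v[:8, 0, 0] = vals
        cube = TminCube(values=v, years=[2000], timestep_hours=3,
                        lat_axis=[50.0], lon_axis=[0.0])
        daily = frost.daily_min(cube)
        assert daily.values[0, 0, 0, 0] == -3.0

    def test_brute_force_oracle(self, tmin_cube):
        daily = frost.daily_min(tmin_cube)
        spd = tmin_cube.samples_per_day
        ny = tmin_cube.years.size
        brute = tmin_cube.values.reshape(
            ny, DAYS_PER_YEAR, spd, *tmin_cube.values.shape[1:]).min(axis=2)
        np.testing.assert_array_equal(daily.values, brute)

    def test_partial_day_rejected(self):
        with pytest.raises(ValueError, match="partial|whole"):
            TminCube(values=np.zeros((DAYS_PER_YEAR * 8 + 3, 1, 1)),
                     years=[2000], timestep_hours=3,
                     lat_axis=[50.0], lon_axis=[0.0])


class TestCountFrostDays:
    def test_no_frost(self):
        daily = make_daily(np.full((1, 365, 1, 1), 5.0))
        assert frost.count_frost_days(daily, 1, 365)[0, 0, 0] == 0

    def test_direct_count(self):
        v = np.full((1, 365, 1, 1), 5.0)
        v[0, 149:159] = -1.0                  # DOY 150-159
        daily = make_daily(v)
        assert frost.count_frost_days(daily, 145, 200)[0, 0, 0] == 10

    def test_exactly_zero_is_not_frost(self):
        v = np.full((1, 365, 1, 1), 0.0)
        daily = make_daily(v)
        assert frost.count_frost_days(daily, 1, 365)[0, 0, 0] == 0

    def test_inverted_window_rejected(self):
        daily = make_daily(np.zeros((1, 365, 1, 1)))
        with pytest.raises(ValueError, match="invalid window"):
            frost.count_frost_days(daily, 200, 100)

    def test_random_windows_match_day_loop_oracle(self):
        rng = np.random.default_rng(42)
        v = rng.normal(2.0, 5.0, size=(3, 365, 2, 2))
        daily = make_daily(v)
        for _ in range(200):
            s = int(rng.integers(1, 300))
            e = int(rng.integers(s, 366))
            got = frost.count_frost_days(daily, s, e)
            for iy in range(3):
                for ilat in range(2):
                    for ilon in range(2):
                        assert got[iy, ilat, ilon] == day_loop_gsfd(
                            v[iy, :, ilat, ilon], s, e)


class TestSplitCounts:
    def _frost_at(self, doys):
        v = np.full((1, 365, 1, 1), 5.0)
        for d in doys:
            v[0, d - 1] = -1.0
        return make_daily(v)

    def test_solstice_definition(self):
        daily = self._frost_at([155, 160, 200])
        spr, fal = frost.split_counts(daily, np.full((1, 1, 1), 150.0),
                                      np.full((1, 1, 1), 250.0), "solstice")
        assert (spr[0, 0, 0], fal[0, 0, 0]) == (2, 1)

    def test_eos_before_solstice(self):
        daily = self._frost_at([150, 160])
        spr, fal = frost.split_counts(daily, np.full((1, 1, 1), 140.0),
                                      np.full((1, 1, 1), 170.0), "solstice")
        assert fal[0, 0, 0] == 0
        assert spr[0, 0, 0] == 2

    def test_sos_after_solstice_all_autumn(self):
        daily = self._frost_at([200, 210])
        spr, fal = frost.split_counts(daily, np.full((1, 1, 1), 190.0),
                                      np.full((1, 1, 1), 250.0), "solstice")
        assert spr[0, 0, 0] == 0
        assert fal[0, 0, 0] == 2

    def test_solstice_day_counts_as_spring(self):
        daily = self._frost_at([SOLSTICE_DOY])
        spr, fal = frost.split_counts(daily, np.full((1, 1, 1), 100.0),
                                      np.full((1, 1, 1), 300.0), "solstice")
        assert spr[0, 0, 0] == 1 and fal[0, 0, 0] == 0

    def test_midseason_repartitions_but_sum_unchanged(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0.0, 3.0, size=(2, 365, 3, 3))
        daily = make_daily(v)
        sos = np.full((2, 3, 3), 100.0)
        eos = np.full((2, 3, 3), 301.0)
        s1, f1 = frost.split_counts(daily, sos, eos, "solstice")
        s2, f2 = frost.split_counts(daily, sos, eos, "midseason")
        np.testing.assert_array_equal(s1 + f1, s2 + f2)
        assert not np.array_equal(s1, s2)  # cutoff 173 vs 200

    def test_missing_phenology_propagates(self):
        daily = self._frost_at([150])
        sos = np.array([[[np.nan]]])
        eos = np.array([[[250.0]]])
        spr, fal = frost.split_counts(daily, sos, eos)
        assert np.isnan(spr[0, 0, 0]) and np.isnan(fal[0, 0, 0])


class TestPartitionAndMonotonicity:
    def test_partition_identity_random(self, daily, ensemble):
        for mode in ("solstice", "midseason"):
            spr, fal = frost.split_counts(daily, ensemble.sos, ensemble.eos,
                                          mode)
            gsfd = frost.count_grid(daily, ensemble, mode).gsfd
            np.testing.assert_array_equal(
                np.where(np.isfinite(gsfd), spr + fal, -1),
                np.where(np.isfinite(gsfd), gsfd, -1))

    def test_window_enlargement_never_decreases_count(self):
        rng = np.random.default_rng(17)
        v = rng.normal(0.0, 4.0, size=(1, 365, 1, 1))
        daily = make_daily(v)
        for _ in range(300):
            s = int(rng.integers(2, 200))
            e = int(rng.integers(s + 1, 365))
            base = frost.count_frost_days(daily, s, e)[0, 0, 0]
            wider = frost.count_frost_days(daily, s - 1, e + 1)[0, 0, 0]
            assert wider >= base


class TestTimingHistograms:
    def test_two_spring_frost_days(self):
        v = np.full((1, 365, 1, 1), 5.0)
        sos = 100
        v[0, sos + 1 - 1] = -1.0       # sos + 1 -> bin 0
        v[0, sos + 12 - 1] = -1.0      # sos + 12 -> bin 1
        daily = make_daily(v)
        h_sos, h_eos = frost.timing_histograms(
            daily, np.full((1, 1, 1), float(sos)),
            np.full((1, 1, 1), 300.0))
        assert h_sos[0] == 1 and h_sos[1] == 1
        assert h_sos.sum() == 2 and h_eos.sum() == 0

    def test_no_frost_all_zero(self):
        daily = make_daily(np.full((1, 365, 1, 1), 5.0))
        h_sos, h_eos = frost.timing_histograms(
            daily, np.full((1, 1, 1), 100.0), np.full((1, 1, 1), 300.0))
        assert h_sos.sum() == 0 and h_eos.sum() == 0

    def test_bin_sums_equal_split_counts(self, daily, ensemble):
        spr, fal = frost.split_counts(daily, ensemble.sos, ensemble.eos)
        h_sos, h_eos = frost.timing_histograms(daily, ensemble.sos,
                                               ensemble.eos)
        assert h_sos.sum() == np.nansum(spr)
        assert h_eos.sum() == np.nansum(fal)


def test_count_grid_invariants(daily, ensemble):
    counts = frost.count_grid(daily, ensemble)
    valid = np.isfinite(counts.gsfd)
    assert np.all(counts.gsfd[valid] >= 0)
    gsl = ensemble.gsl
    assert np.all(counts.gsfd[valid] <= gsl[valid] + 1)
    np.testing.assert_array_equal(counts.gsfd[valid],
                                  (counts.spr_fd + counts.fal_fd)[valid])
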