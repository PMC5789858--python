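"""Phenology extraction: curve fits, threshold dating, ensembles.

The synthetic generator's double-logistic truth serves as the oracle for
parameter-recovery checks; dating rules are additionally exercised on
hand-constructed daily curves.
"""

import numpy as np
import pytest

from frostphen import phenology, synthetic
from frostphen.containers import DAYS_PER_YEAR, PhenologyGrid
from frostphen.phenology import (
    METHODS,
    SeasonalCurve,
    annual_dates,
    climatological_dates,
    ensemble_phenology,
    fit_curve,
    resolve_double_season,
)
from frostphen.synthetic import composite_midpoints, double_logistic

DOYS = composite_midpoints()
DOY_GRID = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)


def season_composites(sos=120.0, eos=280.0, winter=0.1, amp=0.5):
    return double_logistic(DOYS, winter, amp, sos, eos)


def curve_from(values):
    return SeasonalCurve(DOY_GRID, np.asarray(values, float), "manual")


class TestFitCurve:
    def test_double_logistic_recovers_inflections(self):
        c = fit_curve(DOYS, season_composites(), "double_logistic")
        assert c.model_sos == pytest.approx(120, abs=1)
        assert c.model_eos == pytest.approx(280, abs=1)

    def test_piecewise_recovers_inflections(self):
        c = fit_curve(DOYS, season_composites(), "piecewise_logistic")
        assert c.model_sos == pytest.approx(120, abs=2)
        assert c.model_eos == pytest.approx(280, abs=2)

    def test_constant_input_flagged_non_seasonal(self):
        for m in METHODS:
            c = fit_curve(DOYS, np.full(24, 0.3), m)
            assert not c.seasonal
            assert np.isnan(climatological_dates(c)[0])

    def test_hants_peak_near_seasonal_midpoint(self):
        # symmetric season: peak of truth at (sos+eos)/2 = 200
        v = season_composites(sos=140, eos=260)
        c = fit_curve(DOYS, v, "hants")
        assert DOY_GRID[np.argmax(c.fitted_ndvi)] == pytest.approx(200, abs=2)

    def test_too_few_composites_flagged(self):
        v = season_composites()
        v[:6] = np.nan
        c = fit_curve(DOYS, v, "hants")
        assert not c.seasonal

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            fit_curve(DOYS, season_composites(), "spline")


class TestClimatologicalDates:
    @pytest.mark.parametrize("method", METHODS)
    def test_noiseless_truth_recovered(self, method):
        c = fit_curve(DOYS, season_composites(), method)
        sos, eos, thr_sos, _ = climatological_dates(c)
        tol = 2 if method in ("double_logistic", "piecewise_logistic") else 8
        assert sos == pytest.approx(120, abs=tol)
        assert eos == pytest.approx(280, abs=tol)
        # logistic inflection sits at half amplitude
        if method in ("double_logistic", "piecewise_logistic"):
            assert thr_sos == pytest.approx(0.1 + 0.25, abs=0.02)

    def test_mirrored_curve_swaps_roles(self):
        v = double_logistic(DOY_GRID, 0.1, 0.5, 120, 280)
        sos, eos, *_ = climatological_dates(curve_from(v))
        m_sos, m_eos, *_ = climatological_dates(curve_from(v[::-1]))
        # mirror t -> 366 - t maps SOS=120 to EOS=246, EOS=280 to SOS=86
        assert m_sos == pytest.approx(366 - eos, abs=1)
        assert m_eos == pytest.approx(366 - sos, abs=1)

    def test_tie_broken_to_earliest_doy(self):
        # two identical ramps in the first half year -> two equal maxima
        v = np.zeros(DAYS_PER_YEAR)
        v[39:50] = np.linspace(0, 0.5, 11)      # ramp DOY 40-50
        v[50:100] = 0.5
        v[99:110] = np.linspace(0.5, 1.0, 11)   # same slope DOY 100-110
        v[110:183] = 1.0
        v[182:233] = np.linspace(1.0, 0.0, 51)
        sos, _, _, _ = climatological_dates(curve_from(v))
        assert sos <= 50

    def test_monotone_half_year_gives_missing(self):
        v = np.linspace(0.1, 0.8, DAYS_PER_YEAR)  # monotone all year
        sos, eos, *_ = climatological_dates(curve_from(v))
        assert np.isnan(eos)


class TestAnnualDates:
    def test_self_consistency(self):
        c = fit_curve(DOYS, season_composites(), "hants")
        sos_c, eos_c, thr_s, thr_e = climatological_dates(c)
        sos, eos = annual_dates(c, thr_s, thr_e)
        assert sos == pytest.approx(sos_c, abs=1)
        assert eos == pytest.approx(eos_c, abs=1)

    def test_shifted_year_shifts_dates(self):
        clim = fit_curve(DOYS, season_composites(), "double_logistic")
        _, _, thr_s, thr_e = climatological_dates(clim)
        late = fit_curve(DOYS, season_composites(sos=130, eos=290),
                         "double_logistic")
        sos0, eos0 = annual_dates(clim, thr_s, thr_e)
        sos1, eos1 = annual_dates(late, thr_s, thr_e)
        assert sos1 - sos0 == pytest.approx(10, abs=1)
        assert eos1 - eos0 == pytest.approx(10, abs=1)

    def test_threshold_never_reached_gives_missing(self):
        weak = curve_from(double_logistic(DOY_GRID, 0.1, 0.2, 120, 280))
        sos, eos = annual_dates(weak, 0.5, 0.5)
        assert np.isnan(sos) and np.isnan(eos)


class TestDoubleSeason:
    def two_season_curve(self, eos2=330):
        a = double_logistic(DOY_GRID, 0.0, 0.4, 60, 140)
        b = double_logistic(DOY_GRID, 0.0, 0.4, 220, eos2)
        return curve_from(0.1 + a + b)

    def test_unimodal_identity(self):
        c = curve_from(double_logistic(DOY_GRID, 0.1, 0.5, 120, 280))
        rule = resolve_double_season(c)
        assert not rule["bimodal"]
        assert rule["eos_search_end"] == DAYS_PER_YEAR

    def test_two_complete_seasons_span_both(self):
        c = self.two_season_curve(eos2=320)
        rule = resolve_double_season(c)
        assert rule["bimodal"] and rule["second_complete"]
        sos, eos = annual_dates(c, 0.3, 0.3, rule["eos_search_end"])
        assert sos == pytest.approx(60, abs=3)     # first season start
        assert eos == pytest.approx(320, abs=3)    # second season end

    def test_incomplete_second_season_uses_first_only(self):
        c = self.two_season_curve(eos2=420)        # runs past Dec 31
        rule = resolve_double_season(c)
        assert rule["bimodal"] and not rule["second_complete"]
        sos, eos = annual_dates(c, 0.3, 0.3, rule["eos_search_end"])
        assert sos == pytest.approx(60, abs=3)
        assert eos == pytest.approx(140, abs=5)    # first season end


class TestEnsemble:
    def _grid(self, sos_val, eos_val=300.0):
        s = np.full((1, 1, 1), sos_val, dtype=float)
        e = np.full((1, 1, 1), eos_val, dtype=float)
        return PhenologyGrid(sos=s, eos=e, years=[2000], lat_axis=[50.0],
                             lon_axis=[0.0], method="x")

    def test_agreement_passthrough(self):
        grids = {m: self._grid(120.0) for m in METHODS}
        ens = ensemble_phenology(grids)
        assert ens.sos[0, 0, 0] == 120

    def test_mean_of_four(self):
        grids = {m: self._grid(v)
                 for m, v in zip(METHODS, (118.0, 120.0, 122.0, 124.0))}
        assert ensemble_phenology(grids).sos[0, 0, 0] == 121

    def test_minimum_method_coverage(self):
        grids = {m: self._grid(np.nan) for m in METHODS[:3]}
        grids[METHODS[3]] = self._grid(120.0)
        ens = ensemble_phenology(grids, min_methods=2)
        assert np.isnan(ens.sos[0, 0, 0])


@pytest.mark.parametrize("method", METHODS)
def test_shift_equivariance(method):
    """Translating the seasonal cycle by +d days shifts both dates by d."""
    d = 12
    clim = fit_curve(DOYS, season_composites(), method)
    _, _, thr_s, thr_e = climatological_dates(clim)
    base = annual_dates(clim, thr_s, thr_e)
    shifted = fit_curve(DOYS, season_composites(sos=120 + d, eos=280 + d),
                        method)
    moved = annual_dates(shifted, thr_s, thr_e)
    assert moved[0] - base[0] == pytest.approx(d, abs=1)
    assert moved[1] - base[1] == pytest.approx(d, abs=1)


def test_grid_extraction_recovers_truth(truth, ndvi_noiseless, phen_grids):
    years = ndvi_noiseless.years
    sos_true = truth.sos_truth(years)
    eos_true = truth.eos_truth(years)
    ens = phen_grids["ensemble"]
    assert np.isfinite(ens.sos).mean() > 0.95
    assert np.nanmean(np.abs(ens.sos - sos_true)) <= 3
    assert np.nanmean(np.abs(ens.eos - eos_true)) <= 3
    # per-method grids retained alongside the ensemble
    assert set(METHODS) <= set(phen_grids)
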