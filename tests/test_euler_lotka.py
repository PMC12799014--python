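import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stockdemog as sd
from stockdemog.euler_lotka import NoReproductionError
from conftest import leslie_dominant_eigenvalue, random_life_table

FIX_LAMBDA_DEM = 1.1060318580236468  # root of 0.5 x^-2 + 0.8 x^-3 = 1


class TestSolver:
    def test_single_reproductive_age_collapses(self):
        # one age, s=1, f=2: the renewal equation reads lambda = s*f
        assert sd.solve_lambda_from_schedule([1], [1.0], [2.0]) == pytest.approx(2.0)

    def test_stationary_fixture_roots(self, fix_stat_lt):
        assert sd.solve_lambda(fix_stat_lt, include_fishing=True) == pytest.approx(1.0)
        assert sd.solve_lambda(fix_stat_lt, include_fishing=False) == pytest.approx(
            FIX_LAMBDA_DEM, rel=1e-10
        )

    def test_agrees_with_leslie_eigenvalue(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            ages, l, s, fec = random_life_table(rng)
            lam = sd.solve_lambda_from_schedule(ages, s, fec)
            ev = leslie_dominant_eigenvalue(ages, l, fec)
            assert lam == pytest.approx(ev, rel=1e-8)

    @given(guess=st.floats(0.01, 50.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_warm_start_does_not_change_root(self, guess):
        ages = np.arange(1, 6)
        s = np.array([1.0, 0.7, 0.49, 0.343, 0.24])
        fec = np.array([0.0, 0.5, 1.0, 2.0, 2.0])
        base = sd.solve_lambda_from_schedule(ages, s, fec)
        warm = sd.solve_lambda_from_schedule(ages, s, fec, guess=guess)
        assert warm == pytest.approx(base, rel=1e-9)

    def test_no_reproduction_raises(self):
        with pytest.raises(NoReproductionError):
            sd.solve_lambda_from_schedule([1, 2], [1.0, 0.5], [0.0, 0.0])


class TestCalibrateYear:
    def test_stationary_fixture_is_a_fixed_point(self, fix_stat):
        res = sd.calibrate_year(fix_stat, 2003)
        assert res.converged
        assert res.n_iterations == 0
        assert res.adjustment_m == res.adjustment_f == 1.0
        assert res.lambda_real == pytest.approx(1.0)
        assert res.lambda_dem == pytest.approx(FIX_LAMBDA_DEM, rel=1e-9)

    @pytest.mark.parametrize("ratio", [2.0, 0.5])
    def test_matches_geometric_ratio(self, ratio):
        geo = sd.make_geometric_fixture(ratio, 6)
        cfg = sd.CalibrationConfig(tolerance=0.001, step=0.0005)
        res = sd.calibrate_year(geo, 2003, cfg)
        assert res.converged
        assert res.lambda_real == pytest.approx(ratio, rel=0.0015)

    def test_tighter_tolerance_means_more_iterations(self):
        geo = sd.make_geometric_fixture(2.0, 6)
        loose = sd.calibrate_year(geo, 2003, sd.CalibrationConfig(tolerance=0.05, step=0.005))
        tight = sd.calibrate_year(geo, 2003, sd.CalibrationConfig(tolerance=0.001, step=0.0005))
        assert tight.lambda_real == pytest.approx(2.0, rel=0.0015)
        assert abs(loose.lambda_real - 2.0) / 2.0 <= 0.05 + 1e-9
        assert tight.n_iterations > loose.n_iterations

    def test_iteration_cap_flags_not_raises(self):
        geo = sd.make_geometric_fixture(2.0, 6)
        cfg = sd.CalibrationConfig(tolerance=0.001, step=0.0005, max_iterations=3)
        res = sd.calibrate_year(geo, 2003, cfg)
        assert not res.converged

    def test_adjustment_direction_for_growth(self):
        """Matching an upward jump must lower mortality and/or raise
        fecundity, never the reverse."""
        geo = sd.make_geometric_fixture(2.0, 6)
        res = sd.calibrate_year(geo, 2003, sd.CalibrationConfig(tolerance=0.001, step=0.0005))
        assert res.adjustment_m <= 1.0
        assert res.adjustment_f >= 1.0

    def test_step_must_stay_below_tolerance(self):
        with pytest.raises(ValueError):
            sd.CalibrationConfig(tolerance=0.01, step=0.02).validate()


class TestLambdaSeries:
    def test_stationary_fixture_series(self, fix_stat_series):
        # years 2001..2009 calibrate; the terminal year has no successor
        assert len(fix_stat_series.years) == 9
        np.testing.assert_allclose(fix_stat_series.lambda_real, 1.0)
        np.testing.assert_allclose(fix_stat_series.lambda_dem, FIX_LAMBDA_DEM, rtol=1e-9)
        np.testing.assert_allclose(
            fix_stat_series.r_real, np.log(fix_stat_series.lambda_real)
        )

    def test_unfished_stock_equal_bases(self):
        from conftest import stationary_config
        cfg = stationary_config(f_selectivity=np.zeros(3))
        cfg.recruits_per_kg_mean = sd.replacement_rps(cfg)
        t = sd.generate_stock(cfg)
        series = sd.lambda_series(t)
        np.testing.assert_allclose(series.lambda_real, series.lambda_dem, rtol=1e-9)

    def test_geometric_decline_tracks_ratio(self):
        geo = sd.make_geometric_fixture(0.5, 8)
        series = sd.lambda_series(geo)
        assert series.converged.all()
        np.testing.assert_allclose(series.lambda_real, 0.5, rtol=0.055)

    def test_demographic_rate_dominates_realized(self, default_stock):
        series = sd.lambda_series(default_stock)
        assert np.all(series.lambda_dem >= series.lambda_real - 1e-12)
        assert np.all(series.lambda_real > 0)

    def test_converged_years_satisfy_prediction_contract(self, default_stock):
        series = sd.lambda_series(default_stock)
        tol = sd.CalibrationConfig().tolerance
        assert np.all(np.abs(series.pred_error[series.converged]) <= tol + 1e-12)

    @pytest.mark.parametrize("seed", [2, 5])
    def test_abundance_extreme_constraints(self, seed):
        """Calibration pins the growth rate at the observed extremes: at an
        interior maximum-abundance year the rate cannot exceed 1 (+tol), at
        an interior minimum it cannot fall below 1 (-tol)."""
        stock = sd.generate_stock(sd.default_config(seed=seed))
        series = sd.lambda_series(stock)
        tol = sd.CalibrationConfig().tolerance
        totals = stock.total_abundance()
        year_of = dict(zip(series.years, range(len(series.years))))
        i_max = int(np.argmax(totals))
        i_min = int(np.argmin(totals))
        y_max = int(stock.years[i_max])
        y_min = int(stock.years[i_min])
        if y_max in year_of:
            assert series.lambda_real[year_of[y_max]] <= 1 + tol + 1e-9
        if y_min in year_of:
            assert series.lambda_real[year_of[y_min]] >= 1 - tol - 1e-9
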