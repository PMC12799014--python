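import logging

import numpy as np
import pytest

import stockdemog as sd
from stockdemog.life_tables import DegenerateInputError, ScheduleRangeError
from conftest import stationary_config


class TestRecruitmentRate:
    def test_stationary_fixture_value(self, fix_stat):
        # 1000 recruits over 3200 kg of spawning biomass the year before
        assert sd.recruitment_rate(fix_stat, 2003) == pytest.approx(0.3125)

    def test_linear_in_recruits(self, fix_stat):
        doubled = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=np.where(np.arange(3) == 0, 2 * fix_stat.N, fix_stat.N),
            C=fix_stat.C, W=fix_stat.W, Mat=fix_stat.Mat, M=fix_stat.M,
        )
        assert sd.recruitment_rate(doubled, 2003) == pytest.approx(0.625)

    def test_zero_recruits_gives_zero(self, fix_stat):
        N = fix_stat.N.copy()
        N[2, 0] = 0.0
        t = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=N, C=fix_stat.C * 0, W=fix_stat.W, Mat=fix_stat.Mat, M=fix_stat.M,
        )
        assert sd.recruitment_rate(t, 2003) == 0.0

    def test_zero_ssb_is_degenerate(self, fix_stat):
        t = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=fix_stat.N, C=fix_stat.C, W=fix_stat.W,
            Mat=np.zeros_like(fix_stat.Mat), M=fix_stat.M,
        )
        with pytest.raises(DegenerateInputError):
            sd.recruitment_rate(t, 2003)

    def test_lagged_year_outside_span(self, fix_stat):
        with pytest.raises(ScheduleRangeError):
            sd.recruitment_rate(fix_stat, 2001)  # needs SSB in 2000


class TestFecundity:
    def test_stationary_fixture_schedule(self, fix_stat):
        np.testing.assert_allclose(
            sd.fecundity_at_age(fix_stat, 2003), [0.0, 0.625, 1.25]
        )

    def test_biomass_proportional_identity(self, default_stock):
        """At mature ages, per-spawner fecundity reduces to weight times
        the next year's recruitment rate."""
        year = int(default_stock.years[5])
        fec = sd.fecundity_at_age(default_stock, year)
        rps_next = sd.recruitment_rate(default_stock, year + 1)
        iy = default_stock.year_index(year)
        mature = default_stock.Mat[iy] > 0
        np.testing.assert_allclose(
            fec[mature], default_stock.W[iy, mature] * rps_next, rtol=1e-12
        )

    def test_attribution_conserves_recruits(self, default_stock):
        """Summing attributed recruits over spawning ages returns the
        recruit count observed the following year."""
        year = int(default_stock.years[10])
        lt = sd.build_life_table(default_stock, year)
        total_attributed = np.sum(lt.fec * lt.ns)
        observed = default_stock.N[default_stock.year_index(year) + 1, 0]
        assert total_attributed == pytest.approx(observed, rel=1e-10)

    def test_no_spawners_means_zero_fecundity(self, fix_stat):
        t = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=fix_stat.N, C=fix_stat.C, W=fix_stat.W,
            Mat=np.zeros_like(fix_stat.Mat), M=fix_stat.M,
        )
        np.testing.assert_allclose(sd.fecundity_at_age(t, 2003), 0.0)

    def test_per_capita_basis_scales_by_maturity(self, default_stock):
        year = int(default_stock.years[5])
        per_spawner = sd.fecundity_at_age(default_stock, year, basis="per_spawner")
        per_capita = sd.fecundity_at_age(default_stock, year, basis="per_capita")
        iy = default_stock.year_index(year)
        b = default_stock.first_age
        np.testing.assert_allclose(
            per_capita, per_spawner * default_stock.Mat[iy + 1 - b], rtol=1e-12
        )

    def test_final_year_has_no_schedule(self, fix_stat):
        with pytest.raises(ScheduleRangeError):
            sd.fecundity_at_age(fix_stat, int(fix_stat.years[-1]))


class TestMortality:
    def test_stationary_fixture_rates(self, fix_stat):
        F, Z, l = sd.mortality_at_age(fix_stat, 2003)
        np.testing.assert_allclose(F, [0.0, 0.3, 0.3])
        np.testing.assert_allclose(Z, [0.2, 0.5, 0.5])
        np.testing.assert_allclose(l, [0.8, 0.5, 0.5])

    def test_no_catch_means_natural_mortality_only(self, fix_stat):
        t = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=fix_stat.N, C=np.zeros_like(fix_stat.C),
            W=fix_stat.W, Mat=fix_stat.Mat, M=fix_stat.M,
        )
        F, Z, l = sd.mortality_at_age(t, 2003)
        np.testing.assert_allclose(F, 0.0)
        np.testing.assert_allclose(l, 1.0 - fix_stat.M[0])

    def test_total_mortality_at_one_clamps_with_warning(self, fix_stat, caplog):
        C = fix_stat.C.copy()
        C[2, 2] = fix_stat.N[2, 2]  # F = 1 at age 3 => Z = 1.2
        t = sd.StockTable(
            stock_id="X", species="x", region="x",
            years=fix_stat.years, ages=fix_stat.ages,
            N=fix_stat.N, C=C, W=fix_stat.W, Mat=fix_stat.Mat, M=fix_stat.M,
        )
        with caplog.at_level(logging.WARNING):
            F, Z, l = sd.mortality_at_age(t, 2003)
        assert Z[2] >= 1.0
        assert l[2] == pytest.approx(1e-6)
        assert any("clamped" in r.message for r in caplog.records)


class TestSurvivorship:
    def test_cumulative_products(self):
        np.testing.assert_allclose(
            sd.survivorship_to_age(np.array([0.8, 0.5, 0.5])), [1.0, 0.8, 0.4]
        )
        np.testing.assert_allclose(
            sd.survivorship_to_age(np.array([0.8, 0.8, 0.8])), [1.0, 0.8, 0.64]
        )
        np.testing.assert_allclose(sd.survivorship_to_age(np.ones(4)), 1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sd.survivorship_to_age(np.array([]))


class TestBuildLifeTable:
    def test_stationary_fixture_assembly(self, fix_stat_lt):
        lt = fix_stat_lt
        assert (lt.nu, lt.omega) == (2, 3)
        np.testing.assert_allclose(lt.s_real, [1.0, 0.8, 0.4])
        np.testing.assert_allclose(lt.s_dem, [1.0, 0.8, 0.64])
        np.testing.assert_allclose(lt.fec, [0.0, 0.625, 1.25])

    def test_survivorship_ordering(self, default_stock):
        """Fishing can only lower survivorship: s_dem >= s_real, both
        monotonically nonincreasing and 1 at the first age."""
        for year in sd.schedule_years(default_stock)[:5]:
            lt = sd.build_life_table(default_stock, int(year))
            assert lt.s_real[0] == lt.s_dem[0] == 1.0
            assert np.all(lt.s_dem >= lt.s_real - 1e-12)
            assert np.all(np.diff(lt.s_real) <= 1e-12)
            assert np.all(np.diff(lt.s_dem) <= 1e-12)

    def test_unfished_stock_has_equal_survivorships(self):
        cfg = stationary_config(f_selectivity=np.zeros(3))
        cfg.recruits_per_kg_mean = sd.replacement_rps(cfg)
        t = sd.generate_stock(cfg)
        lt = sd.build_life_table(t, int(t.years[3]))
        np.testing.assert_allclose(lt.s_real, lt.s_dem)

    def test_identical_across_years_for_stationary_stock(self, fix_stat):
        tables = [sd.build_life_table(fix_stat, int(y)) for y in sd.schedule_years(fix_stat)]
        for lt in tables[1:]:
            np.testing.assert_allclose(lt.fec, tables[0].fec)
            np.testing.assert_allclose(lt.s_real, tables[0].s_real)


class TestBackfill:
    @staticmethod
    def _age2_stock():
        """Ages 2-3 slice of the stationary fixture (first age b = 2)."""
        fix = sd.make_stationary_fixture(n_years=6)
        return sd.StockTable(
            stock_id="B2", species="x", region="x",
            years=fix.years, ages=np.array([2, 3]),
            N=fix.N[:, 1:], C=fix.C[:, 1:], W=fix.W[:, 1:],
            Mat=fix.Mat[:, 1:], M=fix.M[:, 1:],
        )

    def test_back_calculated_abundance(self):
        t = self._age2_stock()
        filled = sd.backfill_young_ages(t)
        assert filled.first_age == 1
        # N[y-1, 1] = N[y, 2] / (1 - M) = 800 / 0.8 = 1000
        np.testing.assert_allclose(filled.N[:-1, 0], 1000.0)
        np.testing.assert_allclose(filled.C[:, 0], 0.0)
        assert filled.meta["backfilled_ages"] == [1]

    def test_first_age_one_is_noop(self, fix_stat):
        assert sd.backfill_young_ages(fix_stat) is fix_stat

    def test_growth_rates_insensitive_to_backfill(self):
        """Adding a back-calculated age-1 class leaves calibrated growth
        rates essentially unchanged for a stationary stock."""
        t = self._age2_stock()
        filled = sd.backfill_young_ages(t)
        s0 = sd.lambda_series(t)
        s1 = sd.lambda_series(filled)
        common = np.intersect1d(s0.years, s1.years)
        i0 = np.isin(s0.years, common)
        i1 = np.isin(s1.years, common)
        np.testing.assert_allclose(s0.lambda_real[i0], s1.lambda_real[i1], atol=0.06)
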