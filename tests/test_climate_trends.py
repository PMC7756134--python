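"""Theil-Sen trends, ensemble sensitivities, projections, distribution shifts."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thickair import climate_trends as ct, synthetic_data as sd
from thickair.containers import PressureSeries


class TestTheilSen:
    def test_exact_line(self):
        years = np.arange(1980, 2000)
        vals = 0.05 * years + 3.0
        tr = ct.theil_sen(years, vals)
        assert tr.median == pytest.approx(0.5)
        assert tr.lower == pytest.approx(0.5) and tr.upper == pytest.approx(0.5)

    def test_matches_brute_force_median_of_pairwise_slopes(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(6, 50)
            years = np.sort(rng.choice(np.arange(1950, 2020), size=n, replace=False))
            vals = rng.normal(330, 3, n)
            slopes = [
                (vals[j] - vals[i]) / (years[j] - years[i])
                for i, j in combinations(range(n), 2)
            ]
            tr = ct.theil_sen(years, vals)
            assert tr.median == pytest.approx(10 * np.median(slopes), abs=1e-9)

    def test_agrees_with_scipy_estimator(self):
        rng = np.random.default_rng(3)
        years = np.arange(1979, 2020)
        vals = 331 + 0.035 * (years - 1979) + rng.normal(0, 0.8, len(years))
        tr = ct.theil_sen(years, vals)
        scipy_slope = stats.theilslopes(vals, years).slope
        assert tr.median == pytest.approx(10 * scipy_slope, abs=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        years = np.arange(1980, 2010)
        vals = rng.normal(330, 2, len(years))
        a = ct.theil_sen(years, vals)
        b = ct.theil_sen(years, vals + 100.0)
        assert a.median == pytest.approx(b.median)
        assert a.lower == pytest.approx(b.lower)

    def test_robust_to_minority_corruption(self):
        years = np.arange(1980, 2011)
        vals = 0.05 * years + 2.0
        corrupted = vals.copy()
        corrupted[::5][:6] += 50.0  # ~19% of points
        tr = ct.theil_sen(years, corrupted)
        assert tr.median == pytest.approx(0.5, abs=1e-9)

    def test_duplicate_years_handled(self):
        with pytest.raises(ValueError):
            ct.theil_sen([2000, 2000, 2000], [1, 2, 3])

    def test_bootstrap_ci_brackets_truth(self):
        rng = np.random.default_rng(5)
        years = np.arange(1979, 2020)
        vals = 331 + 0.035 * (years - 1979) + rng.normal(0, 0.5, len(years))
        tr = ct.theil_sen(years, vals, ci="bootstrap", n_boot=500, seed=1)
        assert tr.lower <= 0.35 <= tr.upper


class TestSensitivityConversion:
    def test_printed_ratio(self):
        tr = ct.TrendResult(median=0.35, lower=0.23, upper=0.48, n_years=41)
        res = ct.trend_to_sensitivity(tr, 0.17)
        assert res.median == pytest.approx(2.06, abs=0.01)

    def test_zero_trend_and_linearity(self):
        tr0 = ct.TrendResult(median=0.0, lower=0.0, upper=0.0, n_years=41)
        assert ct.trend_to_sensitivity(tr0, 0.17).median == 0.0
        tr2 = ct.TrendResult(median=0.7, lower=0.46, upper=0.96, n_years=41)
        assert ct.trend_to_sensitivity(tr2, 0.17).median == pytest.approx(
            2 * ct.trend_to_sensitivity(
                ct.TrendResult(median=0.35, lower=0.23, upper=0.48, n_years=41), 0.17
            ).median
        )

    def test_zero_temperature_trend_rejected(self):
        tr = ct.TrendResult(median=0.35, lower=0.23, upper=0.48, n_years=41)
        with pytest.raises(ValueError):
            ct.trend_to_sensitivity(tr, 0.0)


class TestEnsembleSensitivity:
    def test_minimum_most_sensitive_with_winter_amplification(self, ensemble_world):
        _, ens, gmt, _ = ensemble_world
        s_min = ct.cmip_sensitivity(ens, gmt, "min").median
        s_max = ct.cmip_sensitivity(ens, gmt, "max").median
        assert s_min > s_max

    def test_constant_temperature_flags_degenerate(self):
        cfg = sd.SyntheticConfig(seed=2, warming_per_decade=0.0,
                                 temperature_noise_sd=0.0)
        ens, gmt, _ = sd.generate_cmip_ensemble(cfg)
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            ct.cmip_sensitivity(ens, gmt, "mean")

    def test_percentile_range_brackets_median(self, ensemble_world):
        _, ens, gmt, _ = ensemble_world
        res = ct.cmip_sensitivity(ens, gmt, "mean")
        assert res.lower <= res.median <= res.upper
        assert len(res.per_model) == 21


class TestProjections:
    def test_zero_warming_identity_and_linearity(self):
        r0 = ct.project_stat(309.0, 2.56, 0.0)
        assert r0.projected_hPa == 309.0
        r1 = ct.project_stat(309.0, 2.56, 1.0)
        r2 = ct.project_stat(309.0, 2.56, 2.0)
        assert r2.projected_hPa - 309.0 == pytest.approx(2 * (r1.projected_hPa - 309.0))

    def test_apparent_elevation_change_for_5hpa_rise(self):
        res = ct.project_stat(309.0, 5.0, 1.0)
        assert res.projected_hPa == pytest.approx(314.0)
        # drop in the height needed to reach the minimum pressure: ~115 m
        assert -res.delta_apparent_elevation_m == pytest.approx(115.0, abs=2.0)

    def test_extrapolation_flag(self):
        assert ct.project_stat(331.0, 2.0, 5.0).extrapolated
        assert not ct.project_stat(331.0, 2.0, 2.0).extrapolated

    def test_warming_to_threshold_inverts_projection(self):
        dT = ct.warming_to_threshold(312.6, 331.0, 2.56)
        assert dT == pytest.approx(7.2, abs=0.05)
        back = ct.project_stat(312.6, 2.56, dT)
        assert back.projected_hPa == pytest.approx(331.0)
        # cooling scenario: annual minimum falling below the feasibility floor
        cool = ct.warming_to_threshold(314.5, 302.0, 2.56)
        assert cool == pytest.approx(-4.9, abs=0.02)

    def test_scenario_backsolve_consistency(self):
        """The two published-style scenarios imply nearly the same current
        annual-minimum statistic."""
        implied_a = 331.0 - 7.2 * 2.56   # from warming-to-mean scenario
        implied_b = 302.0 + 4.9 * 2.56   # from cooling-to-threshold scenario
        assert implied_a == pytest.approx(implied_b, abs=2.0)

    def test_doubling_sensitivity_halves_required_warming(self):
        a = ct.warming_to_threshold(310.0, 320.0, 2.0)
        b = ct.warming_to_threshold(310.0, 320.0, 4.0)
        assert a == pytest.approx(2 * b)


class TestDecadalShift:
    def _hourly(self, years, shift_fn):
        idx = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31 23:00", freq="1h")
        # month-keyed seasonal base so decades with different leap-day
        # counts have identical per-month distributions
        base = 331 + 8 * np.sin(2 * np.pi * idx.month / 12)
        vals = base + shift_fn(idx)
        return PressureSeries(pd.Series(vals, index=idx), elevation=8850)

    def test_identical_decades_zero_difference(self):
        s = self._hourly(range(1980, 2000), lambda idx: 0.0)
        out = ct.decadal_distribution_shift(s, (1980, 1989), (1990, 1999))
        assert np.allclose(out["diff"], 0.0)

    def test_uniform_shift_detected_in_all_quantiles(self):
        shift = lambda idx: np.where(idx.year >= 1990, 1.0, 0.0)
        s = self._hourly(range(1980, 2000), shift)
        out = ct.decadal_distribution_shift(s, (1980, 1989), (1990, 1999))
        assert np.allclose(out["diff"], 1.0)

    def test_monsoon_only_shift(self):
        shift = lambda idx: np.where(
            (idx.year >= 1990) & idx.month.isin([6, 7, 8, 9]), 2.0, 0.0
        )
        s = self._hourly(range(1980, 2000), shift)
        out = ct.decadal_distribution_shift(s, (1980, 1989), (1990, 1999))
        jjas = out.xs(50, level="quantile").loc[[6, 7, 8, 9], "diff"]
        djf = out.xs(50, level="quantile").loc[[12, 1, 2], "diff"]
        assert np.allclose(jjas, 2.0)
        assert np.allclose(djf, 0.0)

    def test_partial_decade_rejected(self):
        s = self._hourly(range(1980, 1995), lambda idx: 0.0)
        with pytest.raises(ValueError):
            ct.decadal_distribution_shift(s, (1980, 1989), (1990, 1999))

    def test_annual_statistics_december_winter_convention(self):
        idx = pd.date_range("2000-01-01", "2002-12-31 23:00", freq="1h")
        vals = np.full(len(idx), 330.0)
        vals[(idx.year == 2000) & (idx.month == 12)] = 310.0
        s = PressureSeries(pd.Series(vals, index=idx), elevation=8850)
        winter = ct.annual_statistics(s, "min", months=[12, 1, 2],
                                      december_to_next_year=True)
        # the Dec-2000 low belongs to winter 2001
        assert winter[2001] == 310.0
        assert winter[2000] == 330.0
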