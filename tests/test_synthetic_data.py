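"""Generators: determinism, prescribed statistics, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from thickair import extremes as ex, reconstruction as rc, synthetic_data as sd


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.SyntheticConfig(winter_sigma=1.0, summer_sigma=2.0)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(gap_fraction=1.0)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(start="2000-01-01", end="1999-01-01")
        with pytest.raises(ValueError):
            sd.SyntheticConfig(oxygenless_ascents=20, total_ascents=10)

    def test_default_seasonal_cycle_hits_monthly_means(self):
        idx = pd.date_range("2001-01-01", "2001-12-31 23:00", freq="1h")
        cyc = pd.Series(sd.seasonal_cycle(idx), index=idx)
        monthly = cyc.groupby(idx.month).mean()
        for month, target in zip(range(1, 13), sd.MONTHLY_MEAN_PRESSURE):
            assert monthly[month] == pytest.approx(target, abs=1.0)
        assert monthly[1] == pytest.approx(323.0, abs=0.5)
        assert monthly[8] == pytest.approx(339.0, abs=0.5)
        assert monthly[8] - monthly[1] == pytest.approx(16.0, abs=0.5)


class TestSummitSeries:
    def test_zero_noise_equals_pure_seasonal_cycle(self):
        cfg = sd.SyntheticConfig(
            start="2000-01-01", end="2000-12-31T23:00",
            winter_sigma=0.0, summer_sigma=0.0, events_per_winter=0.0, seed=1,
        )
        series, _ = sd.generate_summit_series(cfg)
        expect = sd.seasonal_cycle(series.index, np.asarray(cfg.seasonal_coef))
        assert np.allclose(series.values(), expect)

    def test_deterministic_for_fixed_seed(self):
        cfg = sd.SyntheticConfig(start="2000-01-01", end="2001-12-31T23:00", seed=9)
        a, ta = sd.generate_summit_series(cfg)
        b, tb = sd.generate_summit_series(cfg)
        assert np.array_equal(a.values(), b.values())
        assert ta.params["event_times"] == tb.params["event_times"]

    def test_january_mean_near_323(self, default_world):
        _, series, _, _ = default_world
        jan = series.data[series.index.month == 1]
        se = jan.std() / np.sqrt(len(jan) / (24 * 5))  # ~5-day decorrelation
        assert abs(jan.mean() - 323.0) <= max(2 * se, 1.0)

    def test_winter_variability_exceeds_summer(self, default_world):
        _, series, _, _ = default_world
        djf = series.data[series.index.month.isin([12, 1, 2])]
        jja = series.data[series.index.month.isin([7, 8, 9])]
        assert djf.std() > jja.std()
        # winter swings clearly larger than monsoon swings
        assert (djf.max() - djf.min()) > 1.5 * (jja.max() - jja.min())


class TestLevelFields:
    def test_noiseless_fields_roundtrip_to_truth(self, default_world):
        _, series, _, fields = default_world
        rec = rc.reconstruct_summit_series(fields, 8850.0)
        assert np.nanmax(np.abs(rec.values() - series.values())) <= 1e-9

    def test_heights_decrease_with_level_pressure(self, default_world):
        _, _, _, fields = default_world
        z = fields["z"].to_numpy()
        order = np.argsort(fields["level"].to_numpy())
        assert np.all(np.diff(z[:, order, :], axis=1) < 0)

    def test_prescribed_covariate_correlations(self):
        cfg = sd.SyntheticConfig(start="1995-01-01", end="1999-12-31T23:00", seed=11)
        series, truth = sd.generate_summit_series(cfg)
        fields = sd.generate_level_fields(series, config=cfg, truth=truth, n_lon=4)
        idx = series.index
        t = pd.Series(fields["t"].isel(level=0, longitude=0).to_numpy(), index=idx)
        u = pd.Series(fields["u"].isel(level=0, longitude=0).to_numpy(), index=idx)
        months = [12, 1, 2]
        assert (idx.month.isin(months)).sum() >= 10000
        r_t = ex.pressure_covariate_correlation(series, t, months)
        r_u = ex.pressure_covariate_correlation(series, u, months)
        assert r_t == pytest.approx(0.8, abs=0.05)
        assert r_u == pytest.approx(-0.1, abs=0.05)

    def test_summit_outside_levels_rejected(self, default_world):
        _, series, truth, _ = default_world
        with pytest.raises(ValueError):
            sd.generate_level_fields(series, levels=(400, 380), truth=truth)


class TestAWS:
    def test_noiseless_equals_extrapolated_truth(self, default_world):
        _, series, _, _ = default_world
        aws = sd.generate_aws_series(series, 7945.0, 0.0, 0.0, 0.0, seed=1)
        expect = rc.extrapolate_pressure(series.values(), 8850.0, 7945.0, 1.4e-4)
        assert np.allclose(aws.values(), expect)
        assert aws.elevation == 7945.0

    def test_offset_recovery_within_tolerance(self, default_world):
        _, series, _, _ = default_world
        truth_at_station = sd.generate_aws_series(series, 7945.0, 0.0, 0.0, 0.0, seed=1)
        n = 5000
        sub = lambda s: type(s)(s.data.iloc[:n], elevation=s.elevation)
        aws = sd.generate_aws_series(series, 7945.0, 1.5, 0.2, 0.0, seed=2)
        offset = rc.bias_adjustment(sub(truth_at_station), sub(aws))
        assert offset == pytest.approx(1.5, abs=0.05)

    def test_gap_count_exact(self, default_world):
        _, series, _, _ = default_world
        aws = sd.generate_aws_series(series, 7945.0, 0.0, 0.0, 0.3, seed=3)
        n = len(aws)
        assert aws.data.notna().sum() == n - round(0.3 * n)

    def test_gap_fraction_validated(self, default_world):
        _, series, _, _ = default_world
        with pytest.raises(ValueError):
            sd.generate_aws_series(series, 7945.0, 0.0, 0.0, 1.0, seed=1)


class TestEnsemble:
    def test_noiseless_sensitivity_recovered_exactly(self):
        from thickair import climate_trends as ct

        cfg = sd.SyntheticConfig(
            seed=1, n_models=2, sensitivity_mean=2.5, sensitivity_sd=0.0,
            ensemble_noise_sd=0.0, temperature_noise_sd=0.0,
            winter_amplification=0.0,
        )
        ens, gmt, _ = sd.generate_cmip_ensemble(cfg)
        res = ct.cmip_sensitivity(ens, gmt, "mean")
        assert res.median == pytest.approx(2.5, abs=1e-9)

    def test_median_sensitivity_recovery_with_noise(self, ensemble_world):
        from thickair import climate_trends as ct

        _, ens, gmt, truth = ensemble_world
        res = ct.cmip_sensitivity(ens, gmt, "mean")
        assert res.median == pytest.approx(
            truth.params["true_median_sensitivity"], abs=0.15
        )

    def test_too_short_ensemble_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_cmip_ensemble(sd.SyntheticConfig(ensemble_years=30))
        with pytest.raises(ValueError):
            sd.generate_cmip_ensemble(sd.SyntheticConfig(n_models=1))


class TestAscentCatalog:
    def test_totals_and_share(self, default_world):
        _, series, _, _ = default_world
        cfg = sd.SyntheticConfig(start="1995-01-01", end="1998-12-31T23:00", seed=42)
        catalog, _ = sd.generate_ascent_catalog(cfg, series)
        total = catalog["n_climbers"].sum()
        n_ox = catalog.loc[catalog["oxygenless"], "n_climbers"].sum()
        assert total == 10068 and n_ox == 208
        assert round(100 * n_ox / total, 1) == 2.1

    def test_all_weight_on_may(self, default_world):
        _, series, _, _ = default_world
        w = [0.0] * 12
        w[4] = 1.0
        cfg = sd.SyntheticConfig(
            start="1995-01-01", end="1998-12-31T23:00", seed=1,
            oxygenless_month_weights=tuple(w), assisted_month_weights=tuple(w),
        )
        catalog, _ = sd.generate_ascent_catalog(cfg, series)
        assert (pd.DatetimeIndex(catalog["date"]).month == 5).all()

    def test_selection_bias_percentile(self, default_world):
        _, series, _, _ = default_world
        cfg = sd.SyntheticConfig(start="1995-01-01", end="1998-12-31T23:00", seed=7)
        catalog, _ = sd.generate_ascent_catalog(cfg, series)
        ox = catalog[catalog["oxygenless"]]
        may = ox[pd.DatetimeIndex(ox["date"]).month == 5]
        daily = series.data.resample("1D").mean().dropna()
        may_days = daily[daily.index.month == 5]
        ranks = may_days.rank(pct=True) * 100
        dates = pd.DatetimeIndex(may["date"])
        weights = may["n_climbers"].to_numpy()
        mean_pct = np.average(ranks.reindex(dates).to_numpy(), weights=weights)
        assert mean_pct == pytest.approx(70.0, abs=5.0)
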