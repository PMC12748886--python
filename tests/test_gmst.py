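import numpy as np
import pandas as pd
import pytest

from heatattrib import gmst as g


def monthly_frame(values, start_year=1900):
    n = len(values)
    years = start_year + np.arange(n) // 12
    months = np.arange(n) % 12 + 1
    return pd.DataFrame({
        "year": years, "month": months,
        "anomaly": values,
        "anomaly_lower": values - 0.05,
        "anomaly_upper": values + 0.05,
    })


def daily_frame(start, end, tmean, city="c1"):
    dates = pd.date_range(start, end, freq="D")
    t = np.broadcast_to(np.asarray(tmean, dtype=float), dates.shape).copy() \
        if np.ndim(tmean) == 0 else np.asarray(tmean, dtype=float)
    return pd.DataFrame({"city": city, "date": dates, "tmean": t})


class TestSSA:
    def test_constant_series_is_fixed_point(self):
        out = g.ssa_smooth(np.full(300, 2.5), window=20)
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_recovers_noiseless_ramp(self):
        ramp = np.linspace(0.0, 5.0, 400)
        out = g.ssa_smooth(ramp, window=40)
        assert np.max(np.abs(out - ramp)) < 0.01 * np.ptp(ramp)

    def test_denoises_ramp(self, rng):
        ramp = np.linspace(0.0, 3.0, 600)
        noisy = ramp + rng.normal(0.0, 0.1, ramp.size)
        out = g.ssa_smooth(noisy, window=60)
        assert np.sqrt(np.mean((out - ramp) ** 2)) < 0.05

    def test_idempotent_on_smooth_input(self):
        ramp = np.linspace(0.0, 1.0, 400)
        once = g.ssa_smooth(ramp, window=40)
        twice = g.ssa_smooth(once, window=40)
        assert np.max(np.abs(twice - once)) < 1e-6 * np.ptp(ramp)

    def test_removes_subannual_oscillation(self):
        t = np.arange(500.0)
        trend = 0.004 * t
        out = g.ssa_smooth(trend + np.sin(2 * np.pi * t / 12), window=120)
        assert np.max(np.abs(out - trend)) < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 \\* window"):
            g.ssa_smooth(np.arange(100.0), window=60)
        with pytest.raises(ValueError, match="window"):
            g.ssa_smooth(np.arange(100.0), window=1)


class TestRebaselineAndSmoothing:
    def test_shifts_by_reference_mean(self):
        x = np.arange(10.0)
        mask = np.zeros(10, bool)
        mask[:4] = True  # mean 1.5
        out = g.rebaseline(x + 0.3, mask)
        assert np.allclose(out, x + 0.3 - 1.8)

    def test_centered_series_unchanged(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        assert np.allclose(g.rebaseline(x, np.ones(4, bool)), x)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            g.rebaseline(np.arange(5.0), np.zeros(5, bool))

    def test_smooth_gmst_reference_mean_zero(self):
        rng = np.random.default_rng(3)
        n = 60 * 12
        vals = 0.001 * np.arange(n) + rng.normal(0, 0.1, n)
        df = monthly_frame(vals, start_year=1850)
        sm = g.smooth_gmst(df, window=60, reference=(1850, 1880))
        ref = sm[(sm.year >= 1850) & (sm.year <= 1880)]
        for col in ("anomaly", "smoothed", "smoothed_lower", "smoothed_upper"):
            assert abs(ref[col].mean()) < 1e-9
        assert len(sm) == n

    def test_gap_in_months_rejected(self):
        df = monthly_frame(np.zeros(240), start_year=1900)
        df = df.drop(index=100)
        with pytest.raises(ValueError, match="contiguous"):
            g.smooth_gmst(df, window=60, reference=(1900, 1905))


class TestAnnualWarmSeasonMean:
    def test_constant_series(self):
        df = daily_frame("2000-01-01", "2002-12-31", 20.0)
        out = g.annual_warm_season_mean(df)
        assert np.allclose(out.to_numpy(), 20.0)
        assert list(out.index) == [2000, 2001, 2002]

    def test_month_weighted_mean(self):
        dates = pd.date_range("2001-06-01", "2001-09-30", freq="D")
        vals = np.where(np.isin(dates.month, (7, 8)), 20.0, 10.0)
        df = pd.DataFrame({"city": "c", "date": dates, "tmean": vals})
        out = g.annual_warm_season_mean(df)
        # (30*10 + 31*20 + 31*20 + 30*10) / 122
        assert out.loc[2001] == pytest.approx(1840.0 / 122.0, abs=1e-12)

    def test_incomplete_year_excluded(self, caplog):
        df = daily_frame("2000-01-01", "2001-12-31", 15.0)
        df = df[df["date"] != pd.Timestamp("2000-07-04")]
        out = g.annual_warm_season_mean(df)
        assert 2000 not in out.index and 2001 in out.index


class TestScalingFit:
    @staticmethod
    def _series(slope, noise_sd, seed, n=73):
        rng = np.random.default_rng(seed)
        gm = pd.Series(np.linspace(0.0, 1.2, n), index=1950 + np.arange(n))
        t = 15.0 + slope * gm + rng.normal(0.0, noise_sd, n)
        return pd.Series(t.to_numpy(), index=gm.index), gm

    def test_exact_linear_relationship(self):
        t, gm = self._series(1.5, 0.0, 0)
        fit = g.fit_city_scaling(t, gm, years=(1950, 2022))
        assert fit.slope == pytest.approx(1.5, abs=1e-10)
        assert fit.slope_upper - fit.slope_lower == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept == pytest.approx(15.0, abs=1e-8)

    def test_matches_closed_form_ols(self, rng):
        t, gm = self._series(1.5, 0.3, 42)
        fit = g.fit_city_scaling(t, gm, years=(1950, 2022))
        x, y = gm.to_numpy(), t.to_numpy()
        slope_hat = np.sum((x - x.mean()) * (y - y.mean())) / np.sum(
            (x - x.mean()) ** 2
        )
        assert fit.slope == pytest.approx(slope_hat, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        t, gm = self._series(1.5, 0.0, 0)
        with pytest.raises(ValueError, match="variance"):
            g.fit_city_scaling(t, pd.Series(0.5, index=gm.index))

    def test_too_few_years_rejected(self):
        t, gm = self._series(1.5, 0.0, 0, n=8)
        with pytest.raises(ValueError, match="overlapping"):
            g.fit_city_scaling(t, gm, years=(1950, 2022))


def _smoothed_monthly(values_by_month, year_range=(2000, 2001)):
    rows = []
    for y in range(year_range[0], year_range[1] + 1):
        for m in range(1, 13):
            v = values_by_month(m)
            rows.append({"year": y, "month": m, "smoothed": v,
                         "smoothed_lower": v - 0.1, "smoothed_upper": v + 0.1})
    return pd.DataFrame(rows)


class TestCounterfactual:
    def test_zero_slope_is_identity(self):
        daily = daily_frame("2000-01-01", "2001-12-31", 18.0)
        sm = _smoothed_monthly(lambda m: 1.0)
        cf = g.build_counterfactual(daily, 0.0, sm)
        assert np.array_equal(cf["tmean"].to_numpy(), daily["tmean"].to_numpy())

    def test_uniform_gmst_shifts_by_slope(self):
        daily = daily_frame("2000-06-01", "2000-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 1.0)
        cf = g.build_counterfactual(daily, 1.5, sm)
        assert np.allclose(cf["tmean"], 20.0 - 1.5)

    def test_monthly_pattern_oracle(self):
        daily = daily_frame("2000-06-01", "2000-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 0.1 * m)
        cf = g.build_counterfactual(daily, 1.2, sm)
        months = pd.to_datetime(cf["date"]).dt.month.to_numpy()
        assert np.allclose(
            daily["tmean"].to_numpy() - cf["tmean"].to_numpy(), 1.2 * 0.1 * months
        )

    def test_season_only_leaves_winter_untouched(self):
        daily = daily_frame("2000-01-01", "2000-12-31", 10.0)
        sm = _smoothed_monthly(lambda m: 1.0)
        cf = g.build_counterfactual(daily, 2.0, sm)
        months = pd.to_datetime(cf["date"]).dt.month
        days = pd.to_datetime(cf["date"]).dt.day
        in_scope = months.isin((6, 7, 8, 9)) | ((months == 5) & (days >= 22))
        assert np.allclose(cf.loc[~in_scope, "tmean"], 10.0)
        assert np.allclose(cf.loc[in_scope, "tmean"], 8.0)

    def test_missing_month_rejected(self):
        daily = daily_frame("2005-06-01", "2005-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 1.0, year_range=(2000, 2001))
        with pytest.raises(ValueError, match="missing"):
            g.build_counterfactual(daily, 1.0, sm)


class TestEnsemble:
    @staticmethod
    def _fit():
        return g.ScalingFit("c1", 1.5, 0.1, 1.3, 1.7, 15.0, 73)

    def test_nine_members_and_central_identity(self):
        daily = daily_frame("2000-06-01", "2000-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 0.5 + 0.01 * m)
        ens = g.build_ensemble(daily, self._fit(), sm)
        assert len(ens) == 9
        single = g.build_counterfactual(daily, 1.5, sm, gmst_col="smoothed")
        assert np.array_equal(
            ens["cf_central_central"]["tmean"].to_numpy(),
            single["tmean"].to_numpy(),
        )

    def test_degenerate_bounds_collapse(self):
        daily = daily_frame("2000-06-01", "2000-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 0.8)
        sm["smoothed_lower"] = sm["smoothed"]
        sm["smoothed_upper"] = sm["smoothed"]
        fit = g.ScalingFit("c1", 1.5, 0.0, 1.5, 1.5, 15.0, 73)
        ens = g.build_ensemble(daily, fit, sm)
        ref = ens["cf_central_central"]["tmean"].to_numpy()
        for v in ens.values():
            assert np.array_equal(v["tmean"].to_numpy(), ref)

    def test_upper_upper_is_coldest_for_positive_gmst(self):
        daily = daily_frame("2000-06-01", "2000-09-30", 20.0)
        sm = _smoothed_monthly(lambda m: 0.5 + 0.02 * m)
        ens = g.build_ensemble(daily, self._fit(), sm)
        coldest = ens["cf_upper_upper"]["tmean"].to_numpy()
        for name, v in ens.items():
            if name != "cf_upper_upper":
                assert np.all(coldest <= v["tmean"].to_numpy() + 1e-12)


class TestAttributableTemperature:
    def test_identity_when_equal(self):
        daily = daily_frame("2000-01-01", "2001-12-31", 19.0)
        out = g.attributable_temperature(daily, {"cf_central_central": daily})
        assert np.allclose(out["delta_t"], 0.0)

    def test_uniform_shift(self):
        daily = daily_frame("2000-01-01", "2001-12-31", 19.0)
        cf = daily.copy()
        cf["tmean"] -= 1.72
        out = g.attributable_temperature(daily, {"cf_central_central": cf})
        assert np.allclose(out["delta_t"], 1.72)
        assert out.loc["period_mean", "delta_t"] == pytest.approx(1.72)

    def test_linear_in_slope_and_gmst(self):
        daily = daily_frame("2000-01-01", "2000-12-31", 20.0)
        sm = _smoothed_monthly(lambda m: 0.1 * m, year_range=(2000, 2000))
        cf1 = g.build_counterfactual(daily, 1.0, sm)
        cf2 = g.build_counterfactual(daily, 2.0, sm)
        d1 = g.attributable_temperature(daily, {"a": cf1})["delta_t"]
        d2 = g.attributable_temperature(daily, {"a": cf2})["delta_t"]
        assert np.allclose(d2, 2.0 * d1)
        # closed form: beta * warm-season mean of G
        months = pd.date_range("2000-06-01", "2000-09-30").month
        expected = 1.0 * np.mean(0.1 * months)
        assert d1.loc[2000] == pytest.approx(expected, abs=1e-12)


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(g.moving_average_smooth(np.full(9, 3.0), 5), 3.0)

    def test_ramp_interior_identity(self):
        x = np.arange(1.0, 11.0)
        out = g.moving_average_smooth(x, 5)
        assert np.allclose(out[2:-2], x[2:-2])

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=25)
        out = g.moving_average_smooth(x, 5)
        for i in range(25):
            k = min(2, i, 24 - i)
            assert out[i] == pytest.approx(x[i - k : i + k + 1].mean())

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="odd"):
            g.moving_average_smooth(np.arange(10.0), 4)
        with pytest.raises(ValueError, match="length"):
            g.moving_average_smooth(np.arange(3.0), 5)
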