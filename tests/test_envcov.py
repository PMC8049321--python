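"""Front index, Ekman transport, spring transition, seasonal means and lags."""

import numpy as np
import pandas as pd
import pytest

from whaletrends import envcov, synthetic, yearaxis
from whaletrends.envcov import (
    annual_average,
    annual_spring_transitions,
    ekman_transport,
    front_intensity_index,
    lag_series,
    seasonal_average,
    spring_transition,
    wind_to_uv,
)


def make_grid(values_fn, half=25, step=1.0):
    axis = np.arange(-half, half + 1e-9, step)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    return pd.DataFrame({"x_km": gx.ravel(), "y_km": gy.ravel(), "sst": values_fn(gx, gy).ravel()})


class TestFrontIntensityIndex:
    def test_uniform_field_has_zero_gradient(self):
        grid = make_grid(lambda x, y: np.full_like(x, 12.0))
        assert front_intensity_index(grid, 10) == pytest.approx(0.0)

    @pytest.mark.parametrize("radius", [5, 10, 15, 20])
    def test_planar_field_returns_its_slope_at_every_radius(self, radius):
        grid = make_grid(lambda x, y: 0.05 * x)
        assert front_intensity_index(grid, radius) == pytest.approx(0.05)

    def test_step_front_outside_radius_is_invisible(self):
        # SST jumps by delta across x = 12 km; the central-difference stencil
        # with 1 km spacing sees delta/2 at the two columns flanking the jump
        delta = 2.0
        grid = make_grid(lambda x, y: np.where(x > 12, delta, 0.0))
        assert front_intensity_index(grid, 5) == pytest.approx(0.0)
        assert front_intensity_index(grid, 10) == pytest.approx(0.0)
        assert front_intensity_index(grid, 15) == pytest.approx(delta / 2)
        assert front_intensity_index(grid, 20) == pytest.approx(delta / 2)

    def test_disc_not_covered_raises(self):
        grid = make_grid(lambda x, y: x, half=8)
        with pytest.raises(ValueError, match="does not cover"):
            front_intensity_index(grid, 10)

    def test_nondecreasing_in_radius_on_random_fields(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, c = rng.normal(size=3)
            grid = make_grid(lambda x, y: a * x + b * y + 0.01 * c * x * y)
            vals = [front_intensity_index(grid, r) for r in (5, 10, 15, 20)]
            assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))
            assert all(v >= 0 for v in vals)


class TestEkmanTransport:
    def test_zero_wind_zero_transport(self):
        tau, transport = ekman_transport(np.zeros(3), np.zeros(3))
        assert np.allclose(tau, 0) and np.allclose(transport, 0)

    def test_reversed_wind_flips_sign(self):
        u, v = np.array([2.0]), np.array([-6.0])
        _, t1 = ekman_transport(u, v)
        _, t2 = ekman_transport(-u, -v)
        assert t2 == pytest.approx(-t1)

    def test_constant_equatorward_wind_matches_hand_formula(self):
        # 10 kn from the north at 38N along a north-south coast
        u, v = wind_to_uv(np.array([10.0]), np.array([0.0]))
        assert u[0] == pytest.approx(0.0, abs=1e-12)
        assert v[0] == pytest.approx(-10 * 0.514444)
        _, transport = ekman_transport(u, v, latitude_deg=38.0)
        w = 10 * 0.514444
        tau = 1.22 * 1.3e-3 * w * w
        f = 2 * 7.2921159e-5 * np.sin(np.deg2rad(38.0))
        assert transport[0] == pytest.approx(tau / (1025.0 * f) * 100.0)
        assert transport[0] > 0  # equatorward wind is upwelling-favorable

    def test_equatorial_latitude_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            ekman_transport(np.zeros(2), np.zeros(2), latitude_deg=0.5)


class TestSpringTransition:
    def test_piecewise_transport_transition_at_sign_change(self):
        transport = np.where(np.arange(1, 366) <= 80, -1.0, 1.0)
        stb, anomaly = spring_transition(transport)
        assert stb == 80
        assert anomaly == -10

    def test_all_positive_transport_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="monotone"):
            stb, _ = spring_transition(np.ones(365))
        assert stb == 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="300"):
            spring_transition(np.ones(100))

    def test_noisy_reversal_detected_within_three_days_median(self):
        env = synthetic.EnvParams(reversal_day_mean=100.0, reversal_day_sd=0.0)
        stbs = []
        for seed in range(50):
            cfg = synthetic.SimulationConfig(seed=seed, n_years=3, env_params=env)
            wind = synthetic.generate_environment(cfg)["wind"]
            tbl = annual_spring_transitions(wind)
            stbs.extend(tbl["stb_day"].tolist())
        assert abs(np.median(stbs) - 100) <= 3


def monthly_frame(values, start="2000-01"):
    months = pd.period_range(start, periods=len(values), freq="M")
    return pd.DataFrame({"year": months.year, "month": months.month, "value": values})


class TestSeasonalAverage:
    def test_winter_straddles_calendar_years(self):
        # Dec(1999)=12, Jan(2000)=1, Feb(2000)=2 -> winter 2000 = 5
        tbl = monthly_frame([12] + list(range(1, 13)), start="1999-12")
        assert seasonal_average(tbl, "winter", 2000) == pytest.approx(5.0)

    @pytest.mark.parametrize("conv", [yearaxis.CALENDAR, yearaxis.JUNE1])
    @pytest.mark.parametrize("season", list(envcov.SEASONS))
    def test_constant_series_gives_constant(self, conv, season):
        tbl = monthly_frame([7.5] * 48, start="1999-01")
        assert seasonal_average(tbl, season, 2000, year_convention=conv) == pytest.approx(7.5)
        assert annual_average(tbl, 2000, year_convention=conv) == pytest.approx(7.5)

    def test_previous_season_mapping_on_three_year_fixture(self):
        # encode month m of year y as 100*y + m, then check each season picks
        # exactly its member months under both conventions
        months = pd.period_range("1998-01", "2002-12", freq="M")
        tbl = pd.DataFrame(
            {"year": months.year, "month": months.month,
             "value": 100.0 * (months.year - 1998) + months.month}
        )
        # calendar year 2000: winter = Dec 1999, Jan 2000, Feb 2000
        expect = np.mean([100 * 1 + 12, 100 * 2 + 1, 100 * 2 + 2])
        assert seasonal_average(tbl, "winter", 2000) == pytest.approx(expect)
        # previous winter of 2000 = winter of 1999
        expect_prev = np.mean([100 * 0 + 12, 100 * 1 + 1, 100 * 1 + 2])
        assert seasonal_average(tbl, "winter", 1999) == pytest.approx(expect_prev)
        # adjusted year 2000 runs Jun 2000 - May 2001: its winter is
        # Dec 2000, Jan 2001, Feb 2001
        expect_gray = np.mean([100 * 2 + 12, 100 * 3 + 1, 100 * 3 + 2])
        assert seasonal_average(
            tbl, "winter", 2000, year_convention=yearaxis.JUNE1
        ) == pytest.approx(expect_gray)
        # adjusted-year summer sits at the start of the adjusted year
        expect_gray_summer = np.mean([100 * 2 + m for m in (6, 7, 8)])
        assert seasonal_average(
            tbl, "summer", 2000, year_convention=yearaxis.JUNE1
        ) == pytest.approx(expect_gray_summer)

    def test_missing_member_month_raises_with_month_named(self):
        tbl = monthly_frame(list(range(1, 12)), start="2000-01")  # Dec missing
        with pytest.raises(ValueError, match="1999"):
            seasonal_average(tbl, "winter", 2000)

    def test_daily_series_collapse_matches_monthly(self):
        dates = pd.date_range("2000-03-01", "2000-05-31", freq="D")
        daily = pd.DataFrame({"date": dates, "value": dates.month.astype(float)})
        assert seasonal_average(daily, "spring", 2000) == pytest.approx(4.0)


class TestLagSeries:
    def test_two_month_lag_shifts_values(self):
        tbl = monthly_frame([1.0, 2.0, 3.0, 4.0])
        lagged = lag_series(tbl, 2)
        assert lagged["value"].tolist()[2:] == [1.0, 2.0]
        assert lagged["value"].isna().tolist()[:2] == [True, True]

    def test_lag_then_lead_restores(self):
        tbl = monthly_frame(list(np.arange(12.0)))
        lagged = lag_series(tbl, 1)
        restored = lagged.copy()
        restored["value"] = restored["value"].shift(-1)
        assert restored["value"].dropna().tolist() == tbl["value"].tolist()[:-1]

    def test_seasonal_mean_of_lagged_series_matches_hand_shift(self):
        vals = np.arange(1.0, 25.0)
        tbl = monthly_frame(vals, start="2000-01")
        lagged = lag_series(tbl, 2)
        # spring 2001 (Mar, Apr, May 2001) of the lag-2 series = raw Jan, Feb, Mar 2001
        assert seasonal_average(lagged, "spring", 2001) == pytest.approx(np.mean([13, 14, 15]))


class TestCovariateAssembly:
    def test_build_covariates_smoke_and_metadata(self):
        cfg = synthetic.SimulationConfig(seed=0, n_years=4)
        env = synthetic.generate_environment(cfg)
        years = list(cfg.years)
        tbl = envcov.build_covariates(
            env["climate"], env["sea_surface"], env["sst_grid"], env["wind"], years
        )
        assert len(tbl) == 4
        # middle years have complete annual/seasonal values
        mid = tbl[tbl["species_year"] == years[2]].iloc[0]
        assert np.isfinite(mid["sst_annual"]) and np.isfinite(mid["soi_prev_winter"])
        assert np.isfinite(mid["fii_5km"]) and mid["fii_5km"] >= 0
        assert envcov.availability_day("prev_winter") == 0
        assert envcov.availability_day("winter") < envcov.availability_day("summer")
        assert envcov.availability_day("annual") == 365
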