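"""Wet-thermal rate curve and rate-sum accumulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seedbed as sb
from seedbed.germination import RateCurveParams, _validate_series

from conftest import make_series, random_series


class TestRateCurve:
    @pytest.mark.parametrize(
        "temp, psi, expected",
        [
            (-2.0, -0.5, 0.0),  # too cold
            (15.0, -2.0, 0.0),  # too dry
            (0.0, -0.1, 0.0),  # base temperature is a strict bound
            (15.0, -1.25, 0.0),  # wet threshold is a strict bound
            (20.0, -0.1, 0.007449),  # c0 + 20*c1 + 400*c2
            (10.0, -1.0, 1.29e-4 + 6.16e-3 - 1.25e-3),
        ],
    )
    def test_rate_values(self, temp, psi, expected):
        assert sb.germination_rate(temp, psi) == pytest.approx(expected, abs=1e-12)

    def test_intercept_limit_near_zero_celsius(self):
        assert sb.germination_rate(1e-9, -0.1) == pytest.approx(1.29e-4, rel=1e-4)

    def test_linear_form_agrees_at_cold_limit_but_not_at_20c(self):
        linear = RateCurveParams(form="linear")
        assert sb.germination_rate(1e-9, -0.1, linear) == pytest.approx(1.29e-4, rel=1e-4)
        assert sb.germination_rate(20.0, -0.1, linear) != pytest.approx(
            sb.germination_rate(20.0, -0.1), rel=1e-3
        )

    def test_hot_temperatures_clip_to_zero_not_negative(self):
        # the quadratic turns negative above ~49 °C
        assert sb.germination_rate(60.0, -0.1) == 0.0

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            sb.germination_rate(float("nan"), -0.1)

    @given(
        temp=st.floats(-50, 60, allow_nan=False),
        psi=st.floats(-10, 0, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_rate_nonnegative_and_zero_outside_thresholds(self, temp, psi):
        rate = sb.germination_rate(temp, psi)
        assert rate >= 0.0
        if temp <= 0.0 or psi <= -1.25:
            assert rate == 0.0


class TestHourlyRates:
    def test_all_dry_series_is_zero(self):
        series = make_series(np.full(48, 20.0), np.full(48, -5.0))
        assert (sb.hourly_rates(series) == 0).all()

    def test_constant_wet_series_is_constant(self):
        series = make_series(np.full(48, 20.0), np.full(48, -0.1))
        assert np.allclose(sb.hourly_rates(series), sb.germination_rate(20.0, -0.1))

    def test_matches_hour_by_hour_loop(self):
        rng = np.random.default_rng(5)
        series = random_series(rng, n_hours=2000)
        vec = sb.hourly_rates(series).to_numpy()
        loop = np.array(
            [
                sb.germination_rate(t, p)
                for t, p in zip(series["soil_temp_c"], series["soil_wp_mpa"])
            ]
        )
        np.testing.assert_array_equal(vec, loop)

    def test_gap_in_hourly_spacing_names_first_gap(self):
        series = make_series(np.full(10, 15.0), np.full(10, -0.1))
        series = series.drop(index=4).reset_index(drop=True)
        with pytest.raises(ValueError, match=str(series["timestamp"][3])):
            sb.hourly_rates(series)

    def test_positive_water_potential_rejected(self):
        series = make_series([15.0], [0.5])
        with pytest.raises(ValueError, match="water potential"):
            _validate_series(series)


class TestRateSum:
    def test_24_wet_hours_at_20c(self):
        series = make_series(np.full(24, 20.0), np.full(24, -0.1), start="2005-06-01")
        total = sb.rate_sum(series, ("2005-06-01", "2005-06-02"))
        assert total == pytest.approx(0.178776, abs=1e-9)

    def test_disjoint_window_is_zero(self):
        series = make_series(np.full(24, 20.0), np.full(24, -0.1), start="2005-06-01")
        assert sb.rate_sum(series, ("2010-01-01", "2010-02-01")) == 0.0

    def test_partially_covered_window_raises(self):
        series = make_series(np.full(24, 20.0), np.full(24, -0.1), start="2005-06-01")
        with pytest.raises(ValueError, match="outside series coverage"):
            sb.rate_sum(series, ("2005-06-01 12:00", "2005-06-03"))

    def test_empty_window_raises(self):
        series = make_series(np.full(24, 20.0), np.full(24, -0.1), start="2005-06-01")
        with pytest.raises(ValueError, match="non-empty"):
            sb.rate_sum(series, ("2005-06-01", "2005-06-01"))

    def test_window_additivity(self):
        rng = np.random.default_rng(9)
        series = random_series(rng, n_hours=96, start="2005-06-01")
        whole = sb.rate_sum(series, ("2005-06-01", "2005-06-05"))
        first = sb.rate_sum(series, ("2005-06-01", "2005-06-03"))
        second = sb.rate_sum(series, ("2005-06-03", "2005-06-05"))
        assert whole == pytest.approx(first + second, abs=1e-12)

    @given(split=st.integers(1, 95))
    @settings(max_examples=25, derandomize=True)
    def test_window_additivity_any_split(self, split):
        rng = np.random.default_rng(10)
        series = random_series(rng, n_hours=96, start="2005-06-01")
        ts = pd.Timestamp("2005-06-01") + pd.Timedelta(hours=split)
        whole = sb.rate_sum(series, ("2005-06-01", "2005-06-05"))
        parts = sb.rate_sum(series, ("2005-06-01", ts)) + sb.rate_sum(
            series, (ts, "2005-06-05")
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_wetting_a_dry_hour_never_decreases_the_sum(self):
        rng = np.random.default_rng(12)
        series = random_series(rng, n_hours=200, start="2005-06-01")
        window = ("2005-06-01", "2005-06-09")
        base = sb.rate_sum(series, window)
        dry_warm = (series["soil_wp_mpa"] <= -1.25) & (series["soil_temp_c"] > 0)
        idx = series.index[dry_warm][0]
        wetter = series.copy()
        wetter.loc[idx, "soil_wp_mpa"] = -0.1
        assert sb.rate_sum(wetter, window) >= base


class TestMonthlySums:
    def test_monthly_partition_equals_annual_sum(self):
        rng = np.random.default_rng(20)
        series = random_series(rng, n_hours=8760, start="2005-01-01")
        monthly = sb.monthly_rate_sums(series)
        assert len(monthly) == 12
        annual = sb.rate_sum(series, ("2005-01-01", "2006-01-01"))
        assert monthly["rate_sum"].sum() == pytest.approx(annual, abs=1e-9)

    def test_leap_year_february_has_29_days_of_hours(self):
        n = 366 * 24
        series = make_series(np.full(n, 20.0), np.full(n, -0.1), start="2008-01-01")
        monthly = sb.monthly_rate_sums(series).set_index("month")["rate_sum"]
        assert monthly[2] == pytest.approx(29 * 24 * sb.germination_rate(20.0, -0.1))

    def test_partial_boundary_months_dropped_with_warning(self, caplog):
        n = 24 * 40  # Jan complete, Feb partial
        series = make_series(np.full(n, 20.0), np.full(n, -0.1), start="2005-01-01")
        with caplog.at_level("WARNING", logger="seedbed.germination"):
            monthly = sb.monthly_rate_sums(series)
        assert monthly["month"].tolist() == [1]
        assert "partial boundary months" in caplog.text

    def test_only_march_active_gives_nonzero_only_in_march(self):
        ts = pd.date_range("2005-01-01", "2005-12-31 23:00", freq="h")
        psis = np.where(ts.month == 3, -0.1, -5.0)
        series = make_series(np.full(len(ts), 15.0), psis, start="2005-01-01")
        monthly = sb.monthly_rate_sums(series)
        nonzero = monthly.loc[monthly["rate_sum"] > 0, "month"].tolist()
        assert nonzero == [3]


class TestSeasonalSums:
    @staticmethod
    def monthly_frame(rows):
        return pd.DataFrame(rows, columns=["site_id", "year", "month", "rate_sum"])

    def test_fall_attaches_to_following_observation_year(self):
        monthly = self.monthly_frame(
            [("A", 2004, 10, 1.0), ("A", 2004, 11, 2.0), ("A", 2004, 12, 0.5),
             ("A", 2005, 3, 0.8)]
        )
        seasonal = sb.seasonal_rate_sums(monthly, [2005])
        row = seasonal.iloc[0]
        assert row["obs_year"] == 2005
        assert row["fall_rate_sum"] == pytest.approx(3.5, abs=1e-9)
        assert row["spring_rate_sum"] == pytest.approx(0.8, abs=1e-9)

    def test_missing_october_omits_row_with_warning(self, caplog):
        monthly = self.monthly_frame(
            [("A", 2004, 11, 2.0), ("A", 2004, 12, 0.5), ("A", 2005, 3, 0.8)]
        )
        with caplog.at_level("WARNING", logger="seedbed.germination"):
            seasonal = sb.seasonal_rate_sums(monthly, [2005])
        assert seasonal.empty
        assert "incomplete monthly records" in caplog.text
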