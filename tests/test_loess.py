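"""Local regression, pointwise bands, flags and the mean-deviation statistic."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mhconsult import (
    CorrelationEstimate,
    Stratifier,
    WeeklyCountSeries,
    compare,
    loess_fit,
    mean_deviation,
    pointwise_band,
    scale_forecast,
)
from mhconsult.loess import flag_periods

DATA = Path(__file__).parent / "data"


class TestLoessFit:
    @pytest.mark.parametrize("span", [0.17, 0.4, 1.0])
    @pytest.mark.parametrize("degree", [1, 2])
    def test_exact_on_linear_data(self, span, degree):
        x = np.arange(1.0, 97.0)
        y = 3.0 + 2.0 * x
        fit = loess_fit(y, span=span, degree=degree)
        assert np.abs(fit.fitted - y).max() <= 1e-8

    def test_constant_input_gives_constant_fit_zero_se(self):
        fit = loess_fit(np.full(60, 7.0), span=0.3)
        np.testing.assert_allclose(fit.fitted, 7.0, atol=1e-10)
        assert np.abs(fit.se).max() <= 1e-10

    def test_matches_independent_reference_implementation(self):
        ref = pd.read_csv(DATA / "loess_reference_96pt.csv")
        fit = loess_fit(ref["y"].to_numpy(), span=0.17, degree=2)
        assert np.abs(fit.fitted - ref["fitted_ref"]).max() < 1e-6
        assert np.abs(fit.se - ref["se_ref"]).max() < 1e-6

    def test_span_one_degree_one_equals_ordinary_least_squares_on_a_trend(self):
        # on pure linear-trend data the tricube weighting is irrelevant and
        # the local fit coincides with the global OLS line
        x = np.arange(1.0, 81.0)
        y = 5 + 0.4 * x
        fit = loess_fit(y, span=1.0, degree=1)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fit.fitted, intercept + slope * x, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_fit(np.array([1.0, 2.0, 3.0]))

    def test_nan_input_rejected(self):
        y = np.ones(50)
        y[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            loess_fit(y)


class TestPointwiseBand:
    def _fit(self, fitted, se):
        n = len(fitted)
        from mhconsult.loess import LoessFit

        return LoessFit(
            x=np.arange(n), fitted=np.asarray(fitted, float),
            se=np.asarray(se, float), span=0.5, degree=2, residual_scale=1.0,
        )

    def test_zero_se_collapses_band_onto_the_fit(self):
        fit = self._fit([5.0, 6.0], [0.0, 0.0])
        lo, hi = pointwise_band(fit)
        np.testing.assert_array_equal(lo, fit.fitted)
        np.testing.assert_array_equal(hi, fit.fitted)

    def test_999_band_contains_95_band(self):
        fit = self._fit(np.linspace(0, 10, 20), np.linspace(0.1, 2, 20))
        lo99, hi99 = pointwise_band(fit, 0.999)
        lo95, hi95 = pointwise_band(fit, 0.95)
        assert (lo99 <= lo95).all() and (hi99 >= hi95).all()

    def test_999_normal_quantile_is_about_3_29(self):
        fit = self._fit([100.0], [10.0])
        lo, hi = pointwise_band(fit, 0.999)
        assert hi[0] == pytest.approx(132.905, abs=1e-2)
        assert lo[0] == pytest.approx(67.095, abs=1e-2)

    def test_t_quantile_is_wider_at_small_dof(self):
        fit = self._fit([0.0], [1.0])
        _, hi_norm = pointwise_band(fit, 0.999, "normal")
        _, hi_t = pointwise_band(fit, 0.999, "t", dof=8)
        assert hi_t[0] > hi_norm[0]

    def test_level_must_be_a_probability(self):
        fit = self._fit([0.0], [1.0])
        with pytest.raises(ValueError):
            pointwise_band(fit, 1.2)


class TestMeanDeviation:
    def test_identical_series_deviate_zero(self):
        assert mean_deviation([5, 5, 5], [5, 5, 5]) == 0.0

    def test_absolute_differences_do_not_cancel(self):
        assert mean_deviation([110, 90], [100, 100]) == pytest.approx(10.0)

    def test_uniform_excess_ratio(self):
        pred = np.arange(1.0, 53.0)
        assert mean_deviation(1.5 * pred, pred) == pytest.approx(50.0)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.poisson(100, 50) + 0.0, rng.poisson(100, 50) + 1.0
        assert mean_deviation(obs, pred) == pytest.approx(
            mean_deviation(7 * obs, 7 * pred)
        )

    def test_zero_predicted_total_is_an_error(self):
        with pytest.raises(ValueError):
            mean_deviation([1, 2], [0, 0])


class TestFlagPeriods:
    def test_periods_partition_flagged_weeks_and_are_maximal(self):
        weeks = [(2020, w) for w in range(11, 21)]
        flags = ["none", "above", "above", "none", "below", "below", "above",
                 "none", "none", "above"]
        periods = flag_periods(weeks, flags)
        covered = []
        for p in periods:
            i0, i1 = weeks.index(p.start), weeks.index(p.end)
            assert i0 <= i1
            covered.extend(range(i0, i1 + 1))
            assert all(flags[i] == p.direction for i in range(i0, i1 + 1))
            # maximality: neighbours differ
            assert i0 == 0 or flags[i0 - 1] != p.direction
            assert i1 == len(weeks) - 1 or flags[i1 + 1] != p.direction
        assert sorted(covered) == [i for i, f in enumerate(flags) if f != "none"]


def _forecast_pair(pred_2020, pred_2021, diagnosis="P74"):
    est = CorrelationEstimate(1.0, 0.0, 10, 10, 0, (2017, 2018))
    src = WeeklyCountSeries(
        diagnosis, Stratifier(), [(2019, w, int(c)) for w, c in enumerate(pred_2020[:52], 1)]
    )
    f1 = scale_forecast(src, est, 2020)
    src2 = WeeklyCountSeries(
        diagnosis, Stratifier(), [(2019, w, int(c)) for w, c in enumerate(pred_2021, 1)]
    )
    f2 = scale_forecast(src2, est, 2021)
    return f1, f2


def _observed_series(values_2020, values_2021, diagnosis="P74"):
    points = [(2020, w, int(v)) for w, v in enumerate(values_2020, 1)]
    points += [(2021, w, int(v)) for w, v in enumerate(values_2021, 1)]
    return WeeklyCountSeries(diagnosis, Stratifier(), points)


class TestCompare:
    def test_observed_equal_to_predicted_flags_nothing(self):
        base = 200 + 30 * np.sin(2 * np.pi * np.arange(52) / 52)
        base = np.round(base)
        obs = _observed_series(np.r_[base, base[-1]], base)
        f1, f2 = _forecast_pair(base, base)
        result = compare(obs, (f1, f2))
        assert result.mean_deviation_pct == 0.0
        assert set(result.significant) == {"none"}
        assert result.periods == ()

    def test_constructed_excess_yields_one_above_period_at_the_right_weeks(self):
        rng = np.random.default_rng(2)
        base = np.round(300 + rng.normal(0, 10, 52))
        obs_2020 = np.r_[base, base[-1]].copy()
        fit_ref = compare(
            _observed_series(np.r_[base, base[-1]], base), _forecast_pair(base, base)[0:2]
        )
        shift = 20 * (fit_ref.ci_upper - fit_ref.predicted_smooth).max()
        obs_2020[19:30] += shift  # weeks 20-30 of 2020
        result = compare(_observed_series(obs_2020, base), _forecast_pair(base, base))
        above = [p for p in result.periods if p.direction == "above"]
        assert len(above) == 1
        flagged = {w for (y, w) in result.window if y == 2020
                   for p in above if p.start <= (y, w) <= p.end}
        assert set(range(22, 29)) <= flagged <= set(range(15, 35))

    def test_window_starts_at_2020_w11(self):
        base = np.round(100 + 20 * np.cos(2 * np.pi * np.arange(52) / 52))
        obs = _observed_series(np.r_[base, base[-1]], base)
        result = compare(obs, _forecast_pair(base, base))
        assert result.window[0] == (2020, 11)
        assert result.window[-1] == (2021, 52)
        assert len(result.window) == 43 + 52

    def test_band_ordering_invariant(self):
        rng = np.random.default_rng(4)
        base = np.round(150 + 25 * np.sin(2 * np.pi * np.arange(52) / 26) + rng.normal(0, 8, 52))
        obs_vals = np.round(base * 1.1)
        result = compare(_observed_series(np.r_[obs_vals, obs_vals[-1]], obs_vals),
                         _forecast_pair(base, base))
        assert (result.ci_lower <= result.predicted_smooth + 1e-9).all()
        assert (result.predicted_smooth <= result.ci_upper + 1e-9).all()

    def test_uncovered_window_is_an_error(self):
        base = np.round(np.full(52, 100.0))
        obs = _observed_series(np.r_[base, base[-1]], base)
        f1, f2 = _forecast_pair(base, base)
        with pytest.raises(ValueError):
            compare(obs, (f1, f2), window_start=(2022, 1))
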