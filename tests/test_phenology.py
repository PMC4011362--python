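"""Degree-day accumulation, voltinism and emergence forecasting."""

import numpy as np
import pandas as pd
import pytest

from athetis.errors import (
    InvalidConstantError,
    MissingDataError,
    ResolutionMismatchError,
)
from athetis.phenology import (
    complete_generations,
    daily_degree_days,
    daily_series,
    forecast_emergence,
    generations_per_year,
    monthly_degree_days,
    monthly_series,
)
from athetis.stages import FORECAST_CYCLE, Stage
from athetis.thermal import ThermalConstants


def _const_series(temp, n=365, start="2011-01-01"):
    return daily_series(pd.date_range(start, periods=n, freq="D"), [temp] * n)


def _tc(stage, C, K):
    return ThermalConstants(stage, C, 0.0, K, 0.0, 1.0, 5)


class TestMonthlyDegreeDays:
    def test_all_cold_months_give_zero(self):
        s = monthly_series([2011] * 3, [1, 2, 3], [5.0, 8.0, 10.84])
        assert monthly_degree_days(s, 10.84) == 0.0

    def test_single_warm_month(self):
        s = monthly_series([2011], [4], [20.84])  # April: 30 days
        assert monthly_degree_days(s, 10.84) == pytest.approx(300.0)

    def test_reaccumulates_constructed_annual_total(self):
        # a monthly year whose warm-season excesses sum to 2183.34 DD
        months = list(range(1, 13))
        tm = [0.0, 2.0, 8.0, 14.0, 20.0, 25.0, 27.0, 26.0, 21.0, 15.0, 7.0, 2.0]
        s = monthly_series([2011] * 12, months, tm)
        partial = monthly_degree_days(s, 10.84)
        # top up July so the annual total is exactly the target
        tm[6] += (2183.34 - partial) / 31.0
        s2 = monthly_series([2011] * 12, months, tm)
        assert monthly_degree_days(s2, 10.84) == pytest.approx(2183.34)
        assert generations_per_year(2183.34, 574.08) == 3.80

    def test_daily_series_rejected(self):
        with pytest.raises(ResolutionMismatchError):
            monthly_degree_days(_const_series(20.0), 10.84)

    def test_leap_february_has_29_days(self):
        s = monthly_series([2012], [2], [11.84])
        assert monthly_degree_days(s, 10.84) == pytest.approx(29.0)


class TestDailyDegreeDays:
    def test_at_threshold_contributes_zero(self):
        traj = daily_degree_days(_const_series(10.84, n=10), 10.84)
        assert (traj == 0.0).all()

    def test_constant_warm_series(self):
        traj = daily_degree_days(_const_series(20.84, n=58), 10.84)
        assert traj.iloc[-1] == pytest.approx(580.0)
        crossing = int(np.searchsorted(traj.values, 574.08)) + 1  # 1-based day
        assert crossing == 58

    def test_mixed_days(self):
        s = daily_series(pd.date_range("2011-05-01", periods=5),
                         [9.0, 10.0, 12.0, 15.0, 8.0])
        assert daily_degree_days(s, 10.84).iloc[-1] == pytest.approx(5.32)

    def test_gap_raises(self):
        dates = list(pd.date_range("2011-05-01", periods=3)) + [
            pd.Timestamp("2011-05-06")
        ]
        s = daily_series(dates, [15.0] * 4)
        with pytest.raises(MissingDataError):
            daily_degree_days(s, 10.0)

    def test_monthly_series_rejected(self):
        s = monthly_series([2011], [6], [25.0])
        with pytest.raises(ResolutionMismatchError):
            daily_degree_days(s, 10.84)

    def test_additive_over_consecutive_periods_and_monotone(self):
        rng = np.random.default_rng(3)
        temps = rng.uniform(-5, 35, size=200)
        dates = pd.date_range("2011-03-01", periods=200)
        whole = daily_degree_days(daily_series(dates, temps), 10.84)
        first = daily_degree_days(daily_series(dates[:120], temps[:120]), 10.84)
        second = daily_degree_days(daily_series(dates[120:], temps[120:]), 10.84)
        assert whole.iloc[-1] == pytest.approx(
            first.iloc[-1] + second.iloc[-1]
        )
        assert (whole.diff().dropna() >= 0).all()

    def test_raising_threshold_never_increases_total(self):
        rng = np.random.default_rng(4)
        temps = rng.uniform(-5, 35, size=100)
        s = daily_series(pd.date_range("2011-04-01", periods=100), temps)
        totals = [daily_degree_days(s, c).iloc[-1] for c in (5.0, 10.84, 15.0, 20.0)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_monthly_and_daily_agree_on_flat_months(self):
        dates = pd.date_range("2011-06-01", "2011-07-31")
        temps = np.where(dates.month == 6, 22.0, 26.0)
        daily_total = daily_degree_days(daily_series(dates, temps), 10.84).iloc[-1]
        monthly_total = monthly_degree_days(
            monthly_series([2011, 2011], [6, 7], [22.0, 26.0]), 10.84
        )
        assert daily_total == pytest.approx(monthly_total)


class TestGenerationsPerYear:
    @pytest.mark.parametrize(
        "dd,K,expected",
        [(2183.34, 574.08, 3.80), (0.0, 574.08, 0.00), (1148.16, 574.08, 2.00)],
    )
    def test_worked_examples(self, dd, K, expected):
        assert generations_per_year(dd, K) == expected

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(InvalidConstantError):
            generations_per_year(1000.0, 0.0)

    def test_complete_generations_floor(self):
        assert complete_generations(2183.34, 574.08) == 3


class TestForecastEmergence:
    def test_no_accumulation_flags_incomplete(self):
        s = _const_series(10.84, n=100)
        fc = forecast_emergence(
            s, {Stage.PUPA: _tc(Stage.PUPA, 10.84, 100.0)},
            "2011-01-01", 1, cycle=[Stage.PUPA],
        )
        assert fc.events == ()
        assert not fc.complete

    def test_single_stage_transition_day(self):
        s = _const_series(20.84, n=100)
        fc = forecast_emergence(
            s, {Stage.PUPA: _tc(Stage.PUPA, 10.84, 100.0)},
            "2011-01-01", 1, cycle=[Stage.PUPA],
        )
        # 10 DD/day: K reached on the 10th day including the biofix day
        assert fc.events[0].date == pd.Timestamp("2011-01-10").date()
        assert fc.complete

    def test_chained_generation_cycle_spacing(self):
        from athetis.synthetic import CALIBRATED_C, CALIBRATED_K

        constants = {
            s: _tc(s, CALIBRATED_C[s], CALIBRATED_K[s]) for s in FORECAST_CYCLE
        }
        s = _const_series(20.84, n=400)
        fc = forecast_emergence(s, constants, "2011-01-01", 3)
        emergences = fc.emergence_dates
        assert len(emergences) == 3
        gaps = [(b - a).days for a, b in zip(emergences, emergences[1:])]
        # one full cycle needs ~574.08/10 days; per-stage day rounding can
        # add at most one day per stage
        assert all(574.08 / 10 <= g <= 574.08 / 10 + 5 for g in gaps)
        dates = [e.date for e in fc.events]
        assert dates == sorted(dates)

    def test_transition_day_matches_ceiling_on_random_draws(self):
        rng = np.random.default_rng(11)
        s = _const_series(0.0, n=700)  # temperatures set per draw below
        for _ in range(100):
            C = rng.uniform(5.0, 16.0)
            K = rng.uniform(20.0, 600.0)
            T = C + rng.uniform(1.0, 20.0)
            series = _const_series(T, n=700)
            fc = forecast_emergence(
                series, {Stage.PUPA: _tc(Stage.PUPA, C, K)},
                "2011-01-01", 1, cycle=[Stage.PUPA],
            )
            day = (fc.events[0].date - pd.Timestamp("2011-01-01").date()).days + 1
            assert day == int(np.ceil(K / (T - C)))

    def test_biofix_outside_span_rejected(self):
        s = _const_series(20.0, n=30)
        with pytest.raises(ValueError, match="biofix"):
            forecast_emergence(
                s, {Stage.PUPA: _tc(Stage.PUPA, 10.0, 50.0)},
                "2012-06-01", 1, cycle=[Stage.PUPA],
            )
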