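"""The synthetic rearing-experiment and weather generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from athetis.phenology import daily_degree_days, monthly_degree_days
from athetis.stages import REARING_CHAIN, Outcome, Stage
from athetis.synthetic import (
    RearingScenario,
    ideal_scenario,
    monthly_means,
    calibrated_scenario,
    parameter_recovery_replicates,
    simulate_rearing,
    simulate_weather,
    survival_counts,
)


class TestSimulateRearing:
    def test_deterministic_limit_durations_on_observation_grid(self):
        from dataclasses import replace

        sc = replace(ideal_scenario(), observation_interval=1.0 / 3.0)
        recs = simulate_rearing(sc)
        completed = recs.loc[recs["outcome"] == Outcome.COMPLETED.value]
        for _, row in completed.iterrows():
            c, k = sc.stage_truth[Stage(row["stage"])]
            nominal = k / (row["temperature_c"] - c)
            expected = np.ceil(nominal / (1 / 3) - 1e-9) * (1 / 3)
            assert row["duration_days"] == pytest.approx(expected)
            assert row["duration_days"] >= nominal - 1e-9

    def test_seeded_determinism(self):
        a = simulate_rearing(calibrated_scenario(seed=5))
        b = simulate_rearing(calibrated_scenario(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_rearing(calibrated_scenario(seed=6))
        assert not a.equals(c)

    def test_arrest_fractions_within_binomial_bounds(self):
        recs = simulate_rearing(calibrated_scenario(seed=2))
        for temp, p in ((18.0, 0.95), (21.0, 0.70)):
            larvae = recs.loc[
                (recs["temperature_c"] == temp)
                & (recs["stage"] == Stage.LARVA_TOTAL.value)
                & (recs["outcome"] != Outcome.DIED.value)
            ]
            n = len(larvae)
            arrested = int((larvae["outcome"] == Outcome.ARRESTED.value).sum())
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= arrested <= hi

    def test_infeasible_temperature_skips_stage_with_warning(self):
        sc = RearingScenario(
            temperatures=(14.0, 24.0, 27.0),
            stage_truth={Stage.PREPUPA: (15.08, 30.04)},
            survival_probs={},
            arrest_probs={},
        )
        recs = simulate_rearing(sc)
        at_cold = recs.loc[recs["temperature_c"] == 14.0]
        assert at_cold.empty
        assert any("prepupa" in w and "14" in w for w in recs.attrs["warnings"])

    def test_survival_fractions_converge_to_configured(self):
        probs = {Stage.EGG: {27.0: 0.8}}
        sc = RearingScenario(
            temperatures=(27.0,),
            n_per_treatment=2000,
            stage_truth={Stage.EGG: (11.03, 63.51)},
            survival_probs=probs,
            arrest_probs={},
            duration_noise_cv=0.0,
            seed=9,
        )
        recs = simulate_rearing(sc)
        counts = survival_counts(recs)
        row = counts.iloc[0]
        lo, hi = stats.binom.interval(0.99, row["n_entering"], 0.8)
        assert lo <= row["n_advancing"] <= hi


class TestCalibratedScenario:
    def test_generation_truth_matches_reported_constants(self):
        sc = calibrated_scenario()
        c, k = sc.stage_truth[Stage.GENERATION]
        assert c == 10.84
        assert k == 574.08

    def test_first_instar_survival_high_at_midrange(self):
        sc = calibrated_scenario()
        for temp in (24.0, 27.0):
            assert sc.survival_probs[Stage.LARVA_TOTAL][temp] >= 0.9

    def test_fecundity_peaks_at_27(self):
        sc = calibrated_scenario()
        assert max(sc.fecundity_mean, key=sc.fecundity_mean.get) == 27.0
        assert sc.fecundity_mean[27.0] == 345.15

    def test_chain_covers_all_rearing_stages(self):
        sc = calibrated_scenario()
        for stage in REARING_CHAIN:
            assert stage in sc.stage_truth


def test_estimates_unbiased_within_monte_carlo_error():
    """Under 5% duration noise the treatment-mean estimator of (C, K) shows
    no bias beyond Monte-Carlo resolution."""
    frame = parameter_recovery_replicates(n_replicates=200, seed=0)
    for col, true in (("C_hat", frame.attrs["C_true"]),
                      ("K_hat", frame.attrs["K_true"])):
        bias = frame[col].mean() - true
        mc_se = frame[col].std(ddof=1) / np.sqrt(len(frame))
        assert abs(bias) < 2 * mc_se, (col, bias, mc_se)


class TestSimulateWeather:
    def test_constant_limit(self):
        s = simulate_weather(2011, mean_annual=15.0, amplitude=0.0,
                             daily_noise_sd=0.0)
        assert (s.data["tmean_c"] == 15.0).all()
        assert len(s.data) == 365

    def test_noise_free_total_matches_day_loop(self):
        s = simulate_weather(2011, daily_noise_sd=0.0)
        total = daily_degree_days(s, 10.84).iloc[-1]
        brute = sum(max(0.0, t - 10.84) for t in s.data["tmean_c"])
        assert total == pytest.approx(brute)

    def test_default_regime_is_near_four_generations(self):
        from athetis.phenology import generations_per_year

        s = simulate_weather(2011, seed=0)
        total = float(daily_degree_days(s, 10.84).iloc[-1])
        g = generations_per_year(total, 574.08)
        assert 3.4 <= g <= 4.2

    def test_seeded_determinism_and_leap_year(self):
        a = simulate_weather(2012, seed=3)
        b = simulate_weather(2012, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert len(a.data) == 366

    def test_monthly_means_consistent_with_daily(self):
        s = simulate_weather(2011, daily_noise_sd=0.0, seed=0)
        m = monthly_means(s)
        assert len(m.data) == 12
        june = s.data.loc[s.data["date"].dt.month == 6, "tmean_c"].mean()
        assert m.data.loc[m.data["month"] == 6, "tmean_c"].iloc[0] == (
            pytest.approx(june)
        )
        # monthly accumulation of flat-by-construction months stays within
        # a few percent of the daily total
        daily_total = daily_degree_days(s, 10.84).iloc[-1]
        monthly_total = monthly_degree_days(m, 10.84)
        assert monthly_total == pytest.approx(daily_total, rel=0.05)
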