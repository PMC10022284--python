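"""Unit tests for the KDIGO rule engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akidetect.errors import PreconditionError
from akidetect.kdigo import (
    KDIGORuleConfig,
    creatinine_baseline,
    creatinine_stage_value,
    cumulative_max,
    dialysis_stage_at,
    rolling_min_increase,
    stage_series,
    summarize,
    urine_rate,
    urine_stage_at,
)
from akidetect.preprocessing import derive_observation_window
from akidetect.timeline import ObservationWindow

from conftest import T0, brute_force_urine_rate, hourly_urine, make_timeline, ts

CFG = KDIGORuleConfig()


def window_for(timeline):
    return derive_observation_window(timeline)


class TestCreatinineRules:
    def test_baseline_is_first_in_window_value(self):
        t = make_timeline(creat=[(1.0, 1.1), (10.0, 1.4), (20.0, 2.0)])
        assert creatinine_baseline(t.creatinine_series, window_for(t)) == 1.1

    def test_baseline_single_value_and_boundary(self):
        t = make_timeline(creat=[(0.0, 0.9)], vitals_span_h=24)
        assert creatinine_baseline(t.creatinine_series, window_for(t)) == 0.9

    def test_baseline_requires_in_window_value(self):
        t = make_timeline(creat=[(1.0, 1.0)])
        w = ObservationWindow(T0 + pd.Timedelta(hours=2), T0 + pd.Timedelta(hours=4))
        with pytest.raises(PreconditionError):
            creatinine_baseline(t.creatinine_series, w)

    def test_rolling_min_increase_simple(self):
        t = make_timeline(creat=[(0.0, 0.8), (40.0, 1.2)])
        assert rolling_min_increase(t.creatinine_series, ts([40.0])[0]) == pytest.approx(0.4)

    def test_rolling_min_increase_monotone_decreasing_is_zero(self):
        t = make_timeline(creat=[(0.0, 1.4), (10.0, 1.2), (20.0, 1.0)])
        for h in (0.0, 10.0, 20.0):
            assert rolling_min_increase(t.creatinine_series, ts([h])[0]) == pytest.approx(0.0)

    def test_rolling_min_lookback_is_half_open(self):
        # the 1.0 sits 50 h back, outside the 48 h lookback: min is 1.2 itself
        t = make_timeline(creat=[(0.0, 1.0), (50.0, 1.2)])
        assert rolling_min_increase(t.creatinine_series, ts([50.0])[0]) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "value,baseline,delta,expected",
        [
            (2.5, 1.0, 0.0, 2),  # multiplier band [2.0, 3.0)
            (1.0, 1.0, 0.0, 0),  # no change
            (4.2, 2.8, 0.6, 3),  # absolute >= 4.0 with >= 0.5 rise
            (0.9, 0.6, 0.3, 1),  # 0.3 mg/dl rise above rolling minimum
            (1.95, 1.0, 0.0, 1),  # band gap 1.9..2.0 resolved to stage 1
            (2.95, 1.0, 0.0, 2),  # band gap 2.9..3.0 resolved to stage 2
            (3.0, 1.0, 0.0, 3),  # stage-3 multiplier cutoff inclusive
            (1.5, 1.0, 0.0, 1),
            (4.2, 2.8, 0.2, 1),  # value >= 4 but rise < 0.5: only the 1.5x band matters
            (0.8, 1.0, None, 0),  # no record in lookback: delta rule not met
        ],
    )
    def test_staging_table(self, value, baseline, delta, expected):
        assert creatinine_stage_value(value, baseline, delta, CFG) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(PreconditionError):
            creatinine_stage_value(1.0, 0.0, 0.0, CFG)


class TestUrineRules:
    def test_hourly_normal_rate(self):
        t = make_timeline(urine=hourly_urine([0.5] * 6, 80.0), weights=[(0.0, 80.0)])
        rc = urine_rate(ts([6.0])[0], 6.0, t, window_for(t), CFG)
        assert rc is not None
        rate, cov = rc
        assert rate == pytest.approx(0.5)
        assert cov == pytest.approx(1.0)

    def test_long_gap_makes_window_not_evaluable(self):
        # a single record covering a 10 h gap exceeds the 6 h documentation cap
        t = make_timeline(urine=[(10.0, 400.0)], vitals_span_h=12)
        assert urine_rate(ts([10.0])[0], 6.0, t, window_for(t), CFG) is None

    def test_window_before_observation_start_not_evaluable(self):
        t = make_timeline(urine=hourly_urine([0.4] * 8))
        assert urine_rate(ts([3.0])[0], 6.0, t, window_for(t), CFG) is None

    def test_straddling_record_matches_minute_oracle(self):
        hours = [1.5, 3.0, 5.5, 6.5, 9.0]
        vols = [120.0, 110.0, 210.0, 90.0, 180.0]
        t = make_timeline(urine=list(zip(hours, vols)), vitals_span_h=10)
        rc = urine_rate(ts([8.0])[0], 6.0, t, window_for(t), CFG)
        expect = brute_force_urine_rate(hours, vols, 8.0, 6.0, 80.0)
        assert rc[0] == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize(
        "rates,hour,expected",
        [
            ([0.4] * 8, 6.0, 1),  # oliguria from the window start, 6 h in
            ([0.4] * 8, 8.0, 1),
            ([0.4] * 14, 12.0, 2),  # >= 12 h below 0.5
            ([0.2] * 30, 24.0, 3),  # >= 24 h below 0.3
            ([0.2] * 30, 30.0, 3),
            ([0.5] * 8, 8.0, 0),  # boundary: strict inequality
            ([1.0] * 10, 10.0, 0),
        ],
    )
    def test_sustained_oliguria_staging(self, rates, hour, expected):
        t = make_timeline(urine=hourly_urine(rates), vitals_span_h=len(rates))
        assert urine_stage_at(ts([hour])[0], t, window_for(t), CFG) == expected

    def test_recovery_clears_stage(self):
        # 8 h at 0.4 then normal: by hour 16 the trailing 6 h window is clean
        rates = [0.4] * 8 + [1.2] * 10
        t = make_timeline(urine=hourly_urine(rates), vitals_span_h=len(rates))
        w = window_for(t)
        assert urine_stage_at(ts([8.0])[0], t, w, CFG) == 1
        assert urine_stage_at(ts([16.0])[0], t, w, CFG) == 0


class TestDialysisRule:
    def test_persists_from_event(self):
        t = make_timeline(dialysis=[48.0], vitals_span_h=96)
        w = window_for(t)
        assert dialysis_stage_at(ts([72.0])[0], t.dialysis_events, w) == 3

    def test_no_events(self):
        t = make_timeline(vitals_span_h=48)
        w = window_for(t)
        assert dialysis_stage_at(ts([24.0])[0], t.dialysis_events, w) == 0

    def test_strict_onset(self):
        t = make_timeline(dialysis=[48.0], vitals_span_h=96)
        w = window_for(t)
        just_before = T0 + pd.Timedelta(hours=48) - pd.Timedelta(seconds=1)
        assert dialysis_stage_at(just_before, t.dialysis_events, w) == 0


class TestStageSeries:
    def test_higher_stage_wins_at_same_time(self):
        # urine says 2 (12 h at 0.4), creatinine says 1 at the same instant
        rates = [0.4] * 14
        t = make_timeline(
            urine=hourly_urine(rates),
            creat=[(0.0, 1.0), (12.0, 1.6)],
            vitals_span_h=14,
        )
        res = stage_series(t, window_for(t), CFG)
        at_12 = [p for p in res.points if p.time == ts([12.0])[0]]
        assert at_12 and at_12[0].stage == 2 and at_12[0].criterion == "urine"

    def test_tie_precedence_dialysis_over_urine(self):
        rates = [0.2] * 30
        t = make_timeline(urine=hourly_urine(rates), dialysis=[24.0], vitals_span_h=30)
        res = stage_series(t, window_for(t), CFG)
        at_24 = [p for p in res.points if p.time == ts([24.0])[0]]
        assert at_24 and at_24[0].stage == 3 and at_24[0].criterion == "dialysis"

    def test_all_normal_yields_empty_series(self):
        t = make_timeline(
            urine=hourly_urine([1.0] * 48), creat=[(0.0, 1.0), (24.0, 1.1)],
            vitals_span_h=48,
        )
        res = stage_series(t, window_for(t), CFG)
        assert res.points == []
        assert summarize(res).has_aki is False

    def test_points_stay_inside_window(self):
        rates = [0.2] * 40
        t = make_timeline(urine=hourly_urine(rates), vitals_span_h=40)
        res = stage_series(t, window_for(t), CFG)
        for p in res.points:
            assert res.window.contains(p.time)

    def test_determinism(self):
        rates = [0.4] * 20
        t = make_timeline(urine=hourly_urine(rates), creat=[(0.0, 1.0), (10.0, 2.2)],
                          vitals_span_h=20)
        r1 = stage_series(t, window_for(t), CFG)
        r2 = stage_series(t, window_for(t), CFG)
        assert np.array_equal(r1.stages, r2.stages)
        assert r1.points == r2.points

    def test_reducing_urine_never_reduces_stage(self, rng):
        """Monotonicity: less urine can only worsen (or keep) every combined stage."""
        for _ in range(20):
            n = 30
            vols = rng.uniform(20.0, 120.0, n)
            hours = np.arange(1.0, n + 1.0)
            t1 = make_timeline(urine=list(zip(hours, vols)), vitals_span_h=n)
            k = int(rng.integers(0, n))
            vols2 = vols.copy()
            vols2[k] *= rng.uniform(0.0, 0.9)
            t2 = make_timeline(urine=list(zip(hours, vols2)), vitals_span_h=n)
            s1 = stage_series(t1, window_for(t1), CFG)
            s2 = stage_series(t2, window_for(t2), CFG)
            assert np.all(s2.stages >= s1.stages)


class TestCumulativeMax:
    def test_running_max(self):
        assert cumulative_max(np.array([0, 1, 0, 2, 1])).tolist() == [0, 1, 1, 2, 2]

    def test_absorbing_top_stage(self):
        assert cumulative_max(np.array([3, 0, 1])).tolist() == [3, 3, 3]

    @given(st.lists(st.integers(min_value=0, max_value=3), max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_non_decreasing(self, stages):
        out = cumulative_max(np.array(stages, dtype=int))
        assert all(a <= b for a, b in zip(out, out[1:]))


class TestSummarize:
    def test_first_and_max_differ(self):
        # stage 1 by urine at hour 12, stage 3 by dialysis at hour 48
        rates = [1.0] * 6 + [0.4] * 8 + [1.0] * 40
        t = make_timeline(urine=hourly_urine(rates), dialysis=[48.0], vitals_span_h=54)
        res = stage_series(t, window_for(t), CFG)
        s = summarize(res)
        assert s.first_AKI_stage == 1
        assert s.first_criterion_overall == "urine"
        assert s.max_AKI_stage == 3
        assert s.max_AKI_time == ts([48.0])[0]
        assert s.first_AKI_time < s.max_AKI_time

    def test_criteria_at_max_collects_later_criterion(self):
        # urine reaches stage 1 first; creatinine also reaches stage 1 later
        rates = [1.0] * 2 + [0.4] * 8 + [1.0] * 40
        t = make_timeline(
            urine=hourly_urine(rates),
            creat=[(0.0, 1.0), (30.0, 1.6)],
            vitals_span_h=50,
        )
        s = summarize(stage_series(t, window_for(t), CFG))
        assert s.max_AKI_stage == 1
        assert s.criteria_at_max == frozenset({"urine", "creatinine"})
        assert s.first_criterion_at_max == "urine"

    def test_empty_series(self):
        t = make_timeline(urine=hourly_urine([1.0] * 10), vitals_span_h=10)
        s = summarize(stage_series(t, window_for(t), CFG))
        assert s.has_aki is False and s.max_AKI_stage == 0

    def test_summary_invariants_on_random_cohort(self, rng):
        from akidetect.simulate import SimulationConfig, generate_patient

        cfg = SimulationConfig(n_patients=0, seed=9)
        for i in range(30):
            t, _ = generate_patient(cfg, np.random.default_rng([9, i]), f"r{i}")
            s = summarize(stage_series(t, window_for(t), CFG))
            s.validate()  # raises on any ordering violation
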