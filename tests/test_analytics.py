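"""Cohort-level analytics: incidence, evolution, contributions, subgroups."""

import numpy as np
import pandas as pd
import pytest

from akidetect import analytics
from akidetect.analytics import (
    build_cohort_frame,
    criteria_contribution,
    daily_evolution,
    detection_curves,
    format_pct,
    incidence,
    subgroup_table,
    transition_medians,
    underrepresentation,
    underrepresentation_factor,
)
from akidetect.timeline import AKISummary

from conftest import T0, ts


def summary(pid, max_stage, first_stage=None, first_h=None, max_h=None, crits=("urine",)):
    if max_stage == 0:
        return AKISummary(pid, False, None, None, None, 0)
    first_stage = first_stage or max_stage
    first_h = first_h if first_h is not None else 12.0
    max_h = max_h if max_h is not None else first_h
    return AKISummary(
        pid, True, ts([first_h])[0], first_stage, ts([max_h])[0], max_stage,
        criteria_at_max=frozenset(crits), first_criterion_at_max=sorted(crits)[0],
        first_criterion_overall=sorted(crits)[0],
    )


def frame_row(pid, max_stage, reach=None, visit=None, first_h=None, max_h=None,
              crits=("urine",), first_crit=None, los=10.0):
    reach = reach or {}
    visit = visit if visit is not None else reach
    return {
        "patient_id": pid,
        "max_stage": max_stage,
        "first_stage": min([s for s in reach] or [max_stage]) if max_stage else None,
        "first_time_h": first_h if first_h is not None else min(reach.values(), default=np.nan),
        "max_time_h": max_h if max_h is not None else (reach.get(max_stage, np.nan)),
        "reach1_h": reach.get(1, np.nan),
        "reach2_h": reach.get(2, np.nan),
        "reach3_h": reach.get(3, np.nan),
        "visit1_h": visit.get(1, np.nan),
        "visit2_h": visit.get(2, np.nan),
        "visit3_h": visit.get(3, np.nan),
        "los_days": los,
        "criteria_at_max": frozenset(crits) if max_stage else frozenset(),
        "first_criterion_at_max": (first_crit or (sorted(crits)[0] if max_stage else None)),
        "first_criterion_overall": (first_crit or (sorted(crits)[0] if max_stage else None)),
    }


def make_frame(rows):
    return pd.DataFrame(rows).set_index("patient_id")


class TestIncidence:
    def test_small_cohort_arithmetic(self):
        summaries = [
            summary("a", 0), summary("b", 1), summary("c", 2), summary("d", 2),
        ]
        inc = incidence(summaries)
        by = inc.set_index("group")
        assert by.loc["any_aki", "pct"] == 75.0
        assert by.loc["max_stage_2", "pct"] == 50.0

    def test_all_stage_zero(self):
        inc = incidence([summary(f"p{i}", 0) for i in range(5)])
        assert inc.set_index("group").loc["any_aki", "pct"] == 0.0

    def test_printed_count_pair_rounds_to_one_decimal(self):
        assert format_pct(13755, 21045) == 65.4

    def test_empty_cohort_percentages_null(self):
        inc = incidence([])
        assert inc["pct"].isna().all() or (inc["pct"].isnull()).all()


class TestDailyEvolution:
    def test_flow_counts_hand_enumeration(self):
        rows = [
            frame_row("a", 3, reach={1: 10.0, 3: 30.0}, visit={1: 10.0, 3: 30.0}),
            frame_row("b", 1, reach={1: 40.0}),
            frame_row("c", 0),
        ]
        bins, flows = daily_evolution(make_frame(rows), horizon_days=3)
        b = bins.set_index("day")
        # day 1: a at stage 1, b none, c none
        assert b.loc[1, "n_1"] == 1 and b.loc[1, "n_none"] == 2
        # day 2: a at stage 3 (reached 30 h), b at stage 1 (40 h < 48)
        assert b.loc[2, "n_3"] == 1 and b.loc[2, "n_1"] == 1 and b.loc[2, "n_none"] == 1
        f = flows.set_index(["from_day", "from_stage", "to_stage"])["count"]
        assert f.loc[(1, "1", "3")] == 1
        assert f.loc[(1, "none", "1")] == 1
        assert f.loc[(1, "none", "none")] == 1

    def test_flows_conserve_patients(self):
        rows = [frame_row(f"p{i}", 2, reach={1: 5.0 + i, 2: 20.0 + i}) for i in range(7)]
        rows += [frame_row(f"q{i}", 0) for i in range(5)]
        bins, flows = daily_evolution(make_frame(rows), horizon_days=5)
        for day in range(1, 5):
            total = flows[flows["from_day"] == day]["count"].sum()
            assert total == 12

    def test_constant_patients_identity_flows(self):
        rows = [frame_row("a", 1, reach={1: 2.0}), frame_row("b", 0)]
        _, flows = daily_evolution(make_frame(rows), horizon_days=4)
        assert (flows["from_stage"] == flows["to_stage"]).all()


class TestDetectionCurves:
    def test_two_patient_curve(self):
        rows = [
            frame_row("a", 1, reach={1: 12.0}, first_h=12.0, max_h=12.0),
            frame_row("b", 1, reach={1: 72.0}, first_h=72.0, max_h=72.0),
        ]
        curves = detection_curves(make_frame(rows), horizon_days=4, step_days=1.0)
        c = curves.set_index("day")
        assert c.loc[1.0, "frac_first_aki"] == pytest.approx(0.5)
        assert c.loc[3.0, "frac_first_aki"] == pytest.approx(1.0)

    def test_identical_times_identical_curves(self):
        rows = [frame_row("a", 2, reach={2: 30.0}, first_h=30.0, max_h=30.0)]
        curves = detection_curves(make_frame(rows))
        assert np.allclose(curves["frac_first_aki"], curves["frac_max_aki"])

    def test_first_curve_dominates_max_curve(self, rng):
        rows = []
        for i in range(50):
            stage = int(rng.integers(0, 4))
            if stage == 0:
                rows.append(frame_row(f"p{i}", 0))
            else:
                f = float(rng.uniform(1, 200))
                m = float(rng.uniform(f, 300))
                rows.append(frame_row(f"p{i}", stage, reach={stage: m}, first_h=f, max_h=m))
        curves = detection_curves(make_frame(rows))
        assert (curves["frac_first_aki"] >= curves["frac_max_aki"] - 1e-12).all()
        assert curves["frac_first_aki"].is_monotonic_increasing
        assert curves["frac_max_aki"].is_monotonic_increasing


class TestCriteriaContribution:
    def test_single_criterion_rows(self):
        rows = [frame_row("a", 2, reach={2: 20.0}, crits=("urine",))]
        tab = criteria_contribution(make_frame(rows))
        det = tab[tab["block"] == "detection_of_max"].set_index("row")
        assert det.loc["Drop in urine output", "n_aki"] == 1
        first = tab[tab["block"] == "first_detection_of_max"].set_index("row")
        assert first.loc["Drop in urine output", "n_aki"] == 1

    def test_triple_combination_row_label(self):
        rows = [
            frame_row("a", 3, reach={3: 30.0},
                      crits=("urine", "dialysis", "creatinine"), first_crit="dialysis")
        ]
        tab = criteria_contribution(make_frame(rows))
        det = tab[tab["block"] == "detection_of_max"].set_index("row")
        assert det.loc[
            "Drop in urine output and initiation of dialysis and rise in creatinine",
            "n_aki_3",
        ] == 1

    def test_blocks_partition_aki_patients(self, rng):
        combos = list(analytics.COMBO_ROWS)
        rows = []
        for i in range(40):
            stage = int(rng.integers(0, 4))
            if stage == 0:
                rows.append(frame_row(f"p{i}", 0))
                continue
            combo = combos[int(rng.integers(0, len(combos)))]
            if stage < 3 and "dialysis" in combo:
                combo = frozenset({"urine"})
            rows.append(
                frame_row(f"p{i}", stage, reach={stage: 20.0}, crits=tuple(combo),
                          first_crit=sorted(combo)[0])
            )
        frame = make_frame(rows)
        n_aki = int((frame["max_stage"] >= 1).sum())
        tab = criteria_contribution(frame)
        for block in ("detection_of_max", "first_detection_of_max"):
            sub = tab[tab["block"] == block]
            assert sub["n_aki"].sum() == n_aki
            for st in (1, 2, 3):
                assert sub[f"n_aki_{st}"].sum() == int((frame["max_stage"] == st).sum())


class TestTransitionMedians:
    def test_single_patient(self):
        rows = [frame_row("a", 2, visit={1: 12.0, 2: 19.2}, reach={1: 12.0, 2: 19.2})]
        tm = transition_medians(make_frame(rows)).set_index("transition")
        assert tm.loc["1->2", "n"] == 1
        assert tm.loc["1->2", "median_days"] == pytest.approx(0.3)

    def test_direct_jump_contributes_nothing(self):
        rows = [frame_row("a", 2, visit={2: 10.0}, reach={2: 10.0})]
        tm = transition_medians(make_frame(rows)).set_index("transition")
        assert tm.loc["1->2", "n"] == 0
        assert tm.loc["1->2", "median_days"] is None or pd.isna(tm.loc["1->2", "median_days"])

    def test_four_patient_median(self):
        deltas = [4.8, 9.6, 14.4, 24.0]  # hours -> 0.2, 0.4, 0.6, 1.0 days
        rows = [
            frame_row(f"p{i}", 2, visit={1: 10.0, 2: 10.0 + d}, reach={1: 10.0, 2: 10.0 + d})
            for i, d in enumerate(deltas)
        ]
        tm = transition_medians(make_frame(rows)).set_index("transition")
        assert tm.loc["1->2", "n"] == 4
        assert tm.loc["1->2", "median_days"] == pytest.approx(0.5)  # mid of 0.4/0.6

    def test_counts_bounded_by_stage_reach(self, rng):
        rows = []
        for i in range(60):
            stage = int(rng.integers(0, 4))
            reach = {}
            t = 5.0
            for s in range(1, stage + 1):
                if rng.random() < 0.8:
                    reach[s] = t
                    t += float(rng.uniform(1, 40))
            if stage and stage not in reach:
                reach[stage] = t
            rows.append(frame_row(f"p{i}", stage, reach=reach, visit=reach))
        frame = make_frame(rows)
        tm = transition_medians(frame).set_index("transition")
        for i, j in ((1, 2), (1, 3), (2, 3)):
            n_target = int(frame[f"visit{j}_h"].notna().sum())
            assert tm.loc[f"{i}->{j}", "n"] <= n_target


class TestSubgroupTable:
    def _frame(self):
        rows = [frame_row(f"a{i}", 2, reach={2: 20.0}) for i in range(12)]
        rows += [frame_row(f"n{i}", 0) for i in range(12)]
        return make_frame(rows)

    def test_identical_numeric_high_p(self):
        frame = self._frame()
        cov = pd.DataFrame({"age": 70.0}, index=frame.index)
        tab = subgroup_table(frame, cov, kinds={"age": "numeric"})
        assert tab.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_chi2_closed_form(self):
        from akidetect.stats import chi2_independence

        stat, dof, p = chi2_independence([[30, 70], [50, 50]])
        # hand-computed expected counts: 40/60 per row margin
        expected = ((30 - 40) ** 2 / 40 + (70 - 60) ** 2 / 60) * 2
        assert stat == pytest.approx(expected)
        assert dof == 1

    def test_median_iqr_formatting(self):
        frame = self._frame()
        ages = list(range(60, 72)) + list(range(70, 82))
        cov = pd.DataFrame({"age": ages}, index=frame.index)
        tab = subgroup_table(frame, cov, kinds={"age": "numeric"})
        med = np.median(ages[:12])
        assert f"{med:g}" in tab.iloc[0]["aki"]

    def test_categorical_counts(self):
        frame = self._frame()
        cov = pd.DataFrame({"male": [True] * 9 + [False] * 3 + [True] * 6 + [False] * 6},
                           index=frame.index)
        tab = subgroup_table(frame, cov, kinds={"male": "categorical"})
        assert tab.iloc[0]["aki"] == "9 (75.0%)"
        assert tab.iloc[0]["p_value"] is not None


class TestUnderrepresentation:
    def test_printed_count_pair(self):
        assert underrepresentation_factor(13755, 375) == 36.7

    def test_equal_counts(self):
        assert underrepresentation_factor(100, 100) == 1.0

    def test_zero_documented(self):
        assert underrepresentation_factor(10, 0) is None
        summaries = [summary("a", 1)]
        out = underrepresentation(summaries, {"a": False})
        assert out["factor"] is None

    def test_recall_of_documented(self):
        summaries = [summary("a", 1), summary("b", 2), summary("c", 0)]
        out = underrepresentation(summaries, {"a": True, "b": False, "c": True})
        assert out["documented"] == 2
        assert out["documented_also_detected"] == 1
        assert out["recall_of_documented_pct"] == 50.0
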