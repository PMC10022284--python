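"""Cohort-level descriptive analytics on top of per-patient AKI detection.

Everything here consumes the per-patient detection outputs (stage series and
first/max summaries) and produces the descriptive machinery of an AKI cohort
study: incidence by stage, day-by-day evolution of the cumulative maximum
stage with transition flows, cumulative detection curves for first and max
AKI, the criterion-contribution breakdown, stage-transition medians,
subgroup comparison tables with significance tests, and the
documented-versus-detected underrepresentation factor.

Times are handled relative to each patient's observation-window start, so
"day k" always means the k-th day of the individual ICU observation period
(bin ``[k-1, k)`` days, labelled by its end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .kdigo import DetectionResult
from .stats import chi2_independence, wilcoxon_rank_sum
from .timeline import AKISummary

STAGE_CATEGORIES = ("none", "1", "2", "3")

CRITERION_LABEL = {
    "urine": "Drop in urine output",
    "creatinine": "Rise in creatinine",
    "dialysis": "Initiation of dialysis",
}

#: the seven criterion combinations of the max-stage contribution table,
#: in presentation order
COMBO_ROWS = [
    frozenset({"urine"}),
    frozenset({"creatinine"}),
    frozenset({"urine", "creatinine"}),
    frozenset({"urine", "dialysis", "creatinine"}),
    frozenset({"urine", "dialysis"}),
    frozenset({"dialysis"}),
    frozenset({"dialysis", "creatinine"}),
]


def combo_label(combo: frozenset) -> str:
    order = ("urine", "dialysis", "creatinine")
    parts = [CRITERION_LABEL[c] for c in order if c in combo]
    label = " and ".join(parts)
    return label[0].upper() + (label[1:].lower() if len(label) > 1 else "")


def format_pct(count: float, denom: float) -> Optional[float]:
    """Percentage to one decimal place; None for an empty denominator."""
    if denom == 0:
        return None
    return round(100.0 * count / denom, 1)


# ---------------------------------------------------------------------------
# per-patient frame
# ---------------------------------------------------------------------------

def build_cohort_frame(
    results: Iterable[DetectionResult], summaries: Iterable[AKISummary]
) -> pd.DataFrame:
    """One row per patient with everything the cohort tables need.

    Columns: max_stage, first_stage, first_time_h / max_time_h (relative to
    window start), reach{1,2,3}_h (first time cumulative stage >= s),
    visit{1,2,3}_h (first time cumulative stage == s), los_days,
    criteria_at_max, first_criterion_at_max, first_criterion_overall.
    """
    by_id = {s.patient_id: s for s in summaries}
    rows = []
    for r in results:
        s = by_id[r.patient_id]
        start = r.window.start
        reach = r.reached_times_h()
        visit = r.attainment_times_h()
        rows.append(
            {
                "patient_id": r.patient_id,
                "max_stage": s.max_AKI_stage,
                "first_stage": s.first_AKI_stage if s.has_aki else None,
                "first_time_h": (
                    (s.first_AKI_time - start) / pd.Timedelta(hours=1) if s.has_aki else np.nan
                ),
                "max_time_h": (
                    (s.max_AKI_time - start) / pd.Timedelta(hours=1) if s.has_aki else np.nan
                ),
                "reach1_h": reach.get(1, np.nan),
                "reach2_h": reach.get(2, np.nan),
                "reach3_h": reach.get(3, np.nan),
                "visit1_h": visit.get(1, np.nan),
                "visit2_h": visit.get(2, np.nan),
                "visit3_h": visit.get(3, np.nan),
                "los_days": r.window.duration_days,
                "criteria_at_max": s.criteria_at_max,
                "first_criterion_at_max": s.first_criterion_at_max,
                "first_criterion_overall": s.first_criterion_overall,
            }
        )
    columns = [
        "patient_id", "max_stage", "first_stage", "first_time_h", "max_time_h",
        "reach1_h", "reach2_h", "reach3_h", "visit1_h", "visit2_h", "visit3_h",
        "los_days", "criteria_at_max", "first_criterion_at_max",
        "first_criterion_overall",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("patient_id")


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

def incidence(summaries: Iterable[AKISummary]) -> pd.DataFrame:
    """Counts and percentages of max and first AKI stage over the cohort."""
    summaries = list(summaries)
    max_stages = [s.max_AKI_stage for s in summaries]
    first_stages = [s.first_AKI_stage for s in summaries if s.has_aki]
    return _incidence_from_stages(max_stages, first_stages)


def incidence_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Incidence table recomputed from a persisted cohort frame."""
    max_stages = frame["max_stage"].astype(int).tolist()
    first_stages = [int(v) for v in frame["first_stage"].dropna()]
    return _incidence_from_stages(max_stages, first_stages)


def _incidence_from_stages(max_stages: list, first_stages: list) -> pd.DataFrame:
    n = len(max_stages)
    rows = []
    n_aki = sum(1 for s in max_stages if s >= 1)
    rows.append({"group": "any_aki", "count": n_aki, "pct": format_pct(n_aki, n)})
    for st in (0, 1, 2, 3):
        c = max_stages.count(st)
        rows.append({"group": f"max_stage_{st}", "count": c, "pct": format_pct(c, n)})
    for st in (1, 2, 3):
        c = first_stages.count(st)
        rows.append({"group": f"first_stage_{st}", "count": c, "pct": format_pct(c, n)})
    out = pd.DataFrame(rows)
    out.attrs["n_patients"] = n
    return out


# ---------------------------------------------------------------------------
# temporal evolution
# ---------------------------------------------------------------------------

def _stage_at_day(frame: pd.DataFrame, day: int) -> pd.Series:
    """Cumulative max stage attained up to the end of day ``day`` per patient."""
    t = day * 24.0
    stage = pd.Series(0, index=frame.index, dtype=int)
    for s in (1, 2, 3):
        stage[frame[f"reach{s}_h"] < t] = s
    return stage


def daily_evolution(frame: pd.DataFrame, horizon_days: int = 14) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day cumulative-stage counts and day-to-day transition flows.

    Returns ``(bins, flows)``: *bins* has one row per day 1..horizon with
    counts (and percentages) of patients whose cumulative max stage at the
    end of that day is none/1/2/3; *flows* counts patients moving between
    stage categories across consecutive days. Flows conserve patients.
    """
    n = len(frame)
    bin_rows = []
    flow_rows = []
    prev = None
    for day in range(1, horizon_days + 1):
        cur = _stage_at_day(frame, day)
        counts = {c: int((cur == i).sum()) for i, c in enumerate(STAGE_CATEGORIES)}
        row = {"day": day}
        for c in STAGE_CATEGORIES:
            row[f"n_{c}"] = counts[c]
            row[f"pct_{c}"] = format_pct(counts[c], n)
        bin_rows.append(row)
        if prev is not None:
            tab = pd.crosstab(prev, cur)
            for fr in tab.index:
                for to in tab.columns:
                    cnt = int(tab.loc[fr, to])
                    if cnt:
                        flow_rows.append(
                            {
                                "from_day": day - 1,
                                "to_day": day,
                                "from_stage": STAGE_CATEGORIES[fr],
                                "to_stage": STAGE_CATEGORIES[to],
                                "count": cnt,
                            }
                        )
        prev = cur
    return pd.DataFrame(bin_rows), pd.DataFrame(flow_rows)


def detection_curves(
    frame: pd.DataFrame, horizon_days: int = 14, step_days: float = 0.25
) -> pd.DataFrame:
    """Cumulative fraction of the cohort with first / max AKI detected by time t.

    Both curves are empirical cumulative-incidence step functions over the
    whole cohort (patients without AKI never enter the numerator); every
    patient is observed over their full window, so no censoring adjustment
    is needed.
    """
    n = len(frame)
    grid = np.arange(step_days, horizon_days + 1e-9, step_days)
    first = frame["first_time_h"].to_numpy(dtype=float)
    maxt = frame["max_time_h"].to_numpy(dtype=float)
    rows = []
    for d in grid:
        t = d * 24.0
        f = np.nansum(first <= t) / n if n else np.nan
        m = np.nansum(maxt <= t) / n if n else np.nan
        rows.append({"day": round(float(d), 6), "frac_first_aki": f, "frac_max_aki": m})
    return pd.DataFrame(rows)


def transition_medians(frame: pd.DataFrame) -> pd.DataFrame:
    """Median days between first attainment of stage i and of stage j.

    A patient contributes to pair (i, j) only when the cumulative stage curve
    *visits* stage i before stage j (a patient jumping 0 -> 2 contributes to
    no 1 -> j pair).
    """
    rows = []
    for i, j in ((1, 2), (1, 3), (2, 3)):
        ti = frame[f"visit{i}_h"]
        tj = frame[f"visit{j}_h"]
        ok = ti.notna() & tj.notna() & (ti < tj)
        deltas = (tj[ok] - ti[ok]) / 24.0
        rows.append(
            {
                "transition": f"{i}->{j}",
                "n": int(ok.sum()),
                "median_days": round(float(deltas.median()), 1) if ok.any() else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# criterion contributions
# ---------------------------------------------------------------------------

def criteria_contribution(frame: pd.DataFrame) -> pd.DataFrame:
    """Criterion breakdown of max-stage detection, in two blocks.

    Block ``detection_of_max``: each AKI patient is assigned to exactly one
    of seven criterion-combination rows by the set of criteria that *ever*
    indicated their max stage. Block ``first_detection_of_max``: each AKI
    patient is assigned to one of three single-criterion rows by which
    criterion indicated the max stage first. Columns split the AKI patients
    by max stage; percentages use each column's subgroup size.
    """
    aki = frame[frame["max_stage"] >= 1]
    denoms = {"aki": len(aki)}
    for st in (1, 2, 3):
        denoms[f"aki_{st}"] = int((aki["max_stage"] == st).sum())

    def _row(label: str, block: str, mask: pd.Series) -> dict:
        row = {"block": block, "row": label}
        sub = aki[mask]
        row["n_aki"] = len(sub)
        row["pct_aki"] = format_pct(len(sub), denoms["aki"])
        for st in (1, 2, 3):
            c = int((sub["max_stage"] == st).sum())
            row[f"n_aki_{st}"] = c
            row[f"pct_aki_{st}"] = format_pct(c, denoms[f"aki_{st}"])
        return row

    rows = []
    for combo in COMBO_ROWS:
        mask = aki["criteria_at_max"].apply(lambda s: frozenset(s) == combo).astype(bool)
        rows.append(_row(combo_label(combo), "detection_of_max", mask))
    for crit in ("urine", "creatinine", "dialysis"):
        mask = (aki["first_criterion_at_max"] == crit).astype(bool)
        rows.append(_row(CRITERION_LABEL[crit], "first_detection_of_max", mask))
    out = pd.DataFrame(rows)
    out.attrs["denominators"] = denoms
    return out


# ---------------------------------------------------------------------------
# subgroup comparisons
# ---------------------------------------------------------------------------

#: default covariate typing for the subgroup table
DEFAULT_COVARIATE_KINDS = {
    "age": "numeric",
    "male": "categorical",
    "los_days": "numeric",
    "n_drugs": "numeric",
    "nephrotoxic": "categorical",
    "n_comorbidities": "numeric",
}


def _fmt_median_iqr(x: pd.Series) -> Optional[str]:
    x = x.dropna()
    if len(x) == 0:
        return None
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:g} ({q1:g}, {q3:g})"


def subgroup_table(
    frame: pd.DataFrame,
    covariates: pd.DataFrame,
    kinds: Optional[dict] = None,
) -> pd.DataFrame:
    """Covariate summaries by AKI group with AKI-vs-no-AKI significance tests.

    Numeric covariates: median (IQR) per group, Wilcoxon rank-sum p-value.
    Categorical (boolean) covariates: n (%), Pearson chi-squared p-value.
    Groups: total cohort, AKI, no AKI, and each max stage 1..3.
    """
    kinds = kinds or {
        c: DEFAULT_COVARIATE_KINDS.get(c, "numeric") for c in covariates.columns
    }
    cov = covariates.reindex(frame.index)
    groups = {
        "total": pd.Series(True, index=frame.index),
        "aki": frame["max_stage"] >= 1,
        "no_aki": frame["max_stage"] == 0,
        "aki_1": frame["max_stage"] == 1,
        "aki_2": frame["max_stage"] == 2,
        "aki_3": frame["max_stage"] == 3,
    }
    rows = []
    for name, kind in kinds.items():
        x = cov[name]
        row = {"covariate": name, "kind": kind}
        for g, mask in groups.items():
            sub = x[mask]
            if kind == "numeric":
                row[g] = _fmt_median_iqr(sub)
            else:
                c = int(sub.fillna(False).astype(bool).sum())
                pct = format_pct(c, int(mask.sum()))
                row[g] = None if pct is None else f"{c} ({pct}%)"
        a = x[groups["aki"]].dropna()
        b = x[groups["no_aki"]].dropna()
        p = None
        if len(a) and len(b):
            if kind == "numeric":
                _, p = wilcoxon_rank_sum(a.to_numpy(), b.to_numpy())
            else:
                tab = np.array(
                    [
                        [int(a.astype(bool).sum()), int((~a.astype(bool)).sum())],
                        [int(b.astype(bool).sum()), int((~b.astype(bool)).sum())],
                    ]
                )
                if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                    _, _, p = chi2_independence(tab)
        row["p_value"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# documented-vs-detected underrepresentation
# ---------------------------------------------------------------------------

def underrepresentation(
    summaries: Iterable[AKISummary], documented_flags: dict
) -> dict:
    """Documented-vs-detected accounting.

    ``documented_flags`` maps patient_id -> bool (an explicit AKI diagnosis
    is present in the records). Returns detected and documented counts, the
    underrepresentation factor (detected/documented, one decimal; None when
    nothing is documented), and the share of documented cases the detector
    also found (recall-style percentage).
    """
    summaries = list(summaries)
    detected_ids = {s.patient_id for s in summaries if s.has_aki}
    documented_ids = {pid for pid, f in documented_flags.items() if f}
    return underrepresentation_ids(detected_ids, documented_ids)


def underrepresentation_ids(detected_ids: set, documented_ids: set) -> dict:
    n_det, n_doc = len(detected_ids), len(documented_ids)
    overlap = len(detected_ids & documented_ids)
    return {
        "detected": n_det,
        "documented": n_doc,
        "factor": underrepresentation_factor(n_det, n_doc),
        "documented_also_detected": overlap,
        "recall_of_documented_pct": format_pct(overlap, n_doc),
    }


def underrepresentation_factor(n_detected: int, n_documented: int) -> Optional[float]:
    """detected/documented to one decimal; None when nothing is documented."""
    if n_documented == 0:
        return None
    return round(n_detected / n_documented, 1)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """All cohort tables in one bundle, serialisable by pdms_io.write_report."""

    n_patients: int
    incidence: pd.DataFrame
    daily_bins: pd.DataFrame
    transition_flows: pd.DataFrame
    detection_curves: pd.DataFrame
    criteria_contribution: pd.DataFrame
    transition_medians: pd.DataFrame
    subgroup_table: Optional[pd.DataFrame] = None
    underrepresentation: Optional[dict] = None

    def tables(self) -> dict:
        out = {
            "incidence": self.incidence,
            "fig3b_bins": self.daily_bins,
            "fig3b_flows": self.transition_flows,
            "fig3a_curves": self.detection_curves,
            "table3_criteria": self.criteria_contribution,
            "transition_medians": self.transition_medians,
        }
        if self.subgroup_table is not None:
            out["table4_subgroups"] = self.subgroup_table
        return out


def build_report(
    results: list[DetectionResult],
    summaries: list[AKISummary],
    covariates: Optional[pd.DataFrame] = None,
    documented_flags: Optional[dict] = None,
    horizon_days: int = 14,
) -> CohortReport:
    """Assemble the full cohort report from per-patient detection outputs."""
    if len(results) != len(summaries):
        raise PreconditionError("results and summaries must pair up")
    frame = build_cohort_frame(results, summaries)
    return report_from_frame(frame, covariates, documented_flags, horizon_days)


def report_from_frame(
    frame: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    documented_flags: Optional[dict] = None,
    horizon_days: int = 14,
) -> CohortReport:
    """Assemble the cohort report from a (possibly persisted) cohort frame."""
    bins, flows = daily_evolution(frame, horizon_days)
    underrep = None
    if documented_flags is not None:
        detected = set(frame.index[frame["max_stage"] >= 1])
        documented = {pid for pid, f in documented_flags.items() if f}
        underrep = underrepresentation_ids(detected, documented)
    return CohortReport(
        n_patients=len(frame),
        incidence=incidence_from_frame(frame),
        daily_bins=bins,
        transition_flows=flows,
        detection_curves=detection_curves(frame, horizon_days),
        criteria_contribution=criteria_contribution(frame),
        transition_medians=transition_medians(frame),
        subgroup_table=(
            subgroup_table(frame, covariates) if covariates is not None else None
        ),
        underrepresentation=underrep,
    )
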