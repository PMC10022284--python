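"""KDIGO rule engine: stage acute kidney injury from creatinine, urine output and dialysis.

The three criteria are evaluated independently at every evaluation time and
combined by taking the maximum stage:

=====  ==============================================  =========================  =======================
Stage  Serum creatinine                                Urine output               Dialysis
=====  ==============================================  =========================  =======================
1      baseline multiplier in [1.5, 2.0) OR            < 0.5 ml/kg/h over the     —
       >= 0.3 mg/dl rise above the 48 h rolling min    trailing 6 h window
2      baseline multiplier in [2.0, 3.0)               < 0.5 ml/kg/h over the     —
                                                       trailing 12 h window
3      baseline multiplier >= 3.0 OR                   < 0.3 ml/kg/h over the     initiation of
       (value >= 4.0 mg/dl AND 48 h rise >= 0.5)       trailing 24 h window       kidney replacement
=====  ==============================================  =========================  =======================

Conventions chosen where the consensus criteria leave room:

* the creatinine *baseline* is the first value charted inside the observation
  window (pre-admission levels are typically undocumented in a PDMS archive,
  and immediately post-operative creatinine is still close to baseline);
* the absolute-increase rules compare against the rolling minimum over the
  trailing 48 h, not against the admission baseline;
* multiplier bands are the half-open partition [1.5, 2.0), [2.0, 3.0),
  [3.0, inf) — the customary printed upper bounds 1.9 / 2.9 are the inclusive
  rendering of the same partition at one-decimal resolution;
* urine rules use the *window-average* rate over the trailing 6/12/24 h
  window (strict ``<``), with each charted volume accrued uniformly over the
  interval since the previous record, normalised by the (interpolated) body
  weight; a window is evaluable only when it lies inside the observation
  window and documented accrual intervals no longer than
  ``max_documentation_gap`` cover at least ``window_coverage_min`` of it.

Evaluation times are an hourly grid from the window start united with every
record time; the creatinine criterion fires only at creatinine record times,
the dialysis criterion persists from the first in-window event onward.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PreconditionError
from .preprocessing import weight_interpolator
from .timeline import (
    CRITERION_PRECEDENCE,
    AKISummary,
    ObservationWindow,
    PatientTimeline,
    StagePoint,
    hours_since,
)


@dataclass(frozen=True)
class KDIGORuleConfig:
    """Every threshold and window of the staging rules, plus operational tolerances.

    Units: creatinine mg/dl, urine rates ml/kg/h, windows and gaps hours.
    """

    creat_mult_stage1: float = 1.5
    creat_mult_stage2: float = 2.0
    creat_mult_stage3: float = 3.0
    creat_abs_increase_stage1: float = 0.3
    creat_abs_stage3: float = 4.0
    creat_abs_stage3_increase: float = 0.5
    lookback_creat_min: float = 48.0
    urine_rate_low: float = 0.5
    urine_rate_verylow: float = 0.3
    urine_window_stage1: float = 6.0
    urine_window_stage2: float = 12.0
    urine_window_stage3: float = 24.0
    urine_window_cap: float = 48.0
    window_coverage_min: float = 0.7
    max_documentation_gap: float = 6.0
    eval_grid_step: float = 1.0
    default_weight_kg: Optional[float] = None

    def validate(self) -> None:
        if not (0 < self.creat_mult_stage1 < self.creat_mult_stage2 < self.creat_mult_stage3):
            raise ConfigurationError("creatinine multiplier bands must increase with stage")
        if not (
            0 < self.urine_window_stage1 < self.urine_window_stage2 < self.urine_window_stage3
        ):
            raise ConfigurationError("urine windows must increase with stage")
        if not 0 < self.urine_rate_verylow < self.urine_rate_low:
            raise ConfigurationError("urine rate thresholds must be ordered")
        for name in (
            "creat_abs_increase_stage1",
            "creat_abs_stage3",
            "creat_abs_stage3_increase",
            "lookback_creat_min",
            "eval_grid_step",
            "max_documentation_gap",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.window_coverage_min <= 1:
            raise ConfigurationError("window_coverage_min must be in (0, 1]")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "KDIGORuleConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown kdigo config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# creatinine criterion
# ---------------------------------------------------------------------------

def creatinine_baseline(series: pd.Series, window: ObservationWindow) -> float:
    """Baseline creatinine: the earliest value charted inside the window."""
    inside = series[(series.index >= window.start) & (series.index <= window.end)]
    if len(inside) == 0:
        raise PreconditionError("no creatinine value inside observation window")
    return float(inside.iloc[0])


def rolling_min_increase(
    series: pd.Series, t: pd.Timestamp, lookback_h: float = 48.0
) -> Optional[float]:
    """value(t) minus the minimum over the half-open lookback ``(t - lookback, t]``.

    Returns None when no record falls in the lookback (the rule is then
    treated as not met).
    """
    lo = t - pd.Timedelta(hours=lookback_h)
    sel = series[(series.index > lo) & (series.index <= t)]
    if len(sel) == 0:
        return None
    if t not in series.index:
        raise PreconditionError("rolling_min_increase requires a record at t")
    return float(series.loc[t] - sel.min())


def creatinine_stage_value(
    value: float, baseline: float, delta_48h: Optional[float], cfg: KDIGORuleConfig
) -> int:
    """Stage from a single creatinine value (pure rule arithmetic)."""
    if baseline <= 0:
        raise PreconditionError("creatinine baseline must be positive")
    mult = value / baseline
    d = delta_48h if delta_48h is not None else -np.inf
    if mult >= cfg.creat_mult_stage3 or (
        value >= cfg.creat_abs_stage3 and d >= cfg.creat_abs_stage3_increase
    ):
        return 3
    if cfg.creat_mult_stage2 <= mult < cfg.creat_mult_stage3:
        return 2
    if cfg.creat_mult_stage1 <= mult < cfg.creat_mult_stage2 or d >= cfg.creat_abs_increase_stage1:
        return 1
    return 0


def creatinine_stage_at(
    t: pd.Timestamp, series: pd.Series, baseline: float, cfg: KDIGORuleConfig
) -> int:
    """Stage indicated by the creatinine criterion at record time ``t``."""
    if t not in series.index:
        raise PreconditionError("no creatinine record at t")
    delta = rolling_min_increase(series, t, cfg.lookback_creat_min)
    return creatinine_stage_value(float(series.loc[t]), baseline, delta, cfg)


# ---------------------------------------------------------------------------
# urine criterion
# ---------------------------------------------------------------------------

@dataclass
class UrineAccrual:
    """Piecewise-uniform accrual model of the urine charting records.

    Record *i* at time ``t_i`` (hours since window start) carries the volume
    accrued over ``(t_{i-1}, t_i]``; the first record accrues since the window
    start. Cumulative volume and *covered time* (counting only accrual
    intervals no longer than the documentation-gap cap) are piecewise linear
    in time, so window totals reduce to two interpolations.
    """

    knots: np.ndarray  # strictly increasing hours, starting at the accrual origin
    cum_volume: np.ndarray  # ml, same length
    cum_covered: np.ndarray  # hours of documented accrual, same length

    @classmethod
    def build(
        cls, times_h: np.ndarray, volumes: np.ndarray, max_gap_h: float
    ) -> "UrineAccrual":
        times_h = np.asarray(times_h, dtype=float)
        volumes = np.asarray(volumes, dtype=float)
        if len(times_h) == 0:
            z = np.array([0.0])
            return cls(knots=z, cum_volume=np.array([0.0]), cum_covered=np.array([0.0]))
        # first record accrues since the window start; a record at or before
        # the start gets a token interval so its volume stays outside windows
        first_start = 0.0 if times_h[0] > 0 else times_h[0] - 1e-6
        prev = np.concatenate([[first_start], times_h[:-1]])
        lengths = times_h - prev
        covered = np.where(lengths <= max_gap_h, lengths, 0.0)
        knots = np.concatenate([[prev[0]], times_h])
        cum_v = np.concatenate([[0.0], np.cumsum(volumes)])
        cum_c = np.concatenate([[0.0], np.cumsum(covered)])
        return cls(knots=knots, cum_volume=cum_v, cum_covered=cum_c)

    def volume_between(self, a, b):
        va = np.interp(a, self.knots, self.cum_volume)
        vb = np.interp(b, self.knots, self.cum_volume)
        return vb - va

    def covered_between(self, a, b):
        ca = np.interp(a, self.knots, self.cum_covered)
        cb = np.interp(b, self.knots, self.cum_covered)
        return cb - ca


def urine_rate(
    t_end: pd.Timestamp,
    window_h: float,
    timeline: PatientTimeline,
    window: ObservationWindow,
    cfg: KDIGORuleConfig,
) -> Optional[tuple[float, float]]:
    """Window-average urine rate ending at ``t_end``.

    Returns ``(rate ml/kg/h, coverage fraction)`` or None when the window is
    not evaluable (extends before the observation start, or documented
    coverage below ``cfg.window_coverage_min``).
    """
    origin = window.start
    t = float(hours_since(pd.DatetimeIndex([t_end]), origin)[0])
    acc = UrineAccrual.build(
        hours_since(timeline.urine_series.index, origin),
        timeline.urine_series.to_numpy(dtype=float),
        cfg.max_documentation_gap,
    )
    wfun = weight_interpolator(timeline.weight_series, origin, cfg.default_weight_kg)
    rate, cov = _window_rates(acc, np.array([t]), window_h, wfun)
    if np.isnan(rate[0]) or cov[0] < cfg.window_coverage_min:
        return None
    return float(rate[0]), float(cov[0])


def _window_rates(acc: UrineAccrual, t: np.ndarray, window_h: float, weight_fn):
    """Vectorised window-average rates; NaN rate where not evaluable."""
    a = t - window_h
    vol = acc.volume_between(a, t)
    cov = acc.covered_between(a, t) / window_h
    w = np.asarray(weight_fn(t), dtype=float)
    rate = vol / (w * window_h)
    rate = np.where(a < -1e-9, np.nan, rate)  # window precedes observation start
    return rate, cov


# ---------------------------------------------------------------------------
# single-time criterion evaluations (thin wrappers over the engine)
# ---------------------------------------------------------------------------

def urine_stage_at(
    t: pd.Timestamp,
    timeline: PatientTimeline,
    window: ObservationWindow,
    cfg: KDIGORuleConfig,
) -> int:
    """Stage indicated by the urine criterion at time ``t`` (0 when none)."""
    for stage, w_h, thr in (
        (3, cfg.urine_window_stage3, cfg.urine_rate_verylow),
        (2, cfg.urine_window_stage2, cfg.urine_rate_low),
        (1, cfg.urine_window_stage1, cfg.urine_rate_low),
    ):
        rc = urine_rate(t, w_h, timeline, window, cfg)
        if rc is None:
            continue
        rate, cov = rc
        if cov >= cfg.window_coverage_min and rate < thr:
            return stage
    return 0


def dialysis_stage_at(
    t: pd.Timestamp, events: pd.DatetimeIndex, window: ObservationWindow
) -> int:
    """3 from the first in-window dialysis event onward, else 0."""
    inside = events[(events >= window.start) & (events <= window.end)]
    if len(inside) and t >= inside[0]:
        return 3
    return 0


# ---------------------------------------------------------------------------
# full per-patient detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionResult:
    """Stage series for one patient: combined curve plus per-criterion points."""

    patient_id: str
    window: ObservationWindow
    times_h: np.ndarray  # evaluation grid, hours since window start
    stages: np.ndarray  # combined (max over criteria) stage at each time
    cumulative: np.ndarray  # running max of ``stages``
    points: list  # combined StagePoints (stage >= 1 only)
    criterion_points: dict  # criterion -> list[StagePoint]

    def to_timestamp(self, h: float) -> pd.Timestamp:
        return self.window.start + pd.Timedelta(hours=float(h))

    def attainment_times_h(self) -> dict:
        """First hour at which the cumulative stage equals s, for s = 1..3.

        A patient whose cumulative curve jumps straight from 0 to 2 has no
        stage-1 attainment time (the curve never *visits* stage 1).
        """
        out: dict[int, float] = {}
        for s in (1, 2, 3):
            hit = np.nonzero(self.cumulative == s)[0]
            if len(hit):
                out[s] = float(self.times_h[hit[0]])
        return out

    def reached_times_h(self) -> dict:
        """First hour at which the cumulative stage is >= s, for s = 1..3."""
        out: dict[int, float] = {}
        for s in (1, 2, 3):
            hit = np.nonzero(self.cumulative >= s)[0]
            if len(hit):
                out[s] = float(self.times_h[hit[0]])
        return out


def _evaluation_grid(timeline: PatientTimeline, window: ObservationWindow, step_h: float):
    """Hourly grid from window start, united with every record time (clipped)."""
    T = window.duration_hours
    grid = np.arange(0.0, T + 1e-9, step_h)
    extra = [
        hours_since(timeline.creatinine_series.index, window.start),
        hours_since(timeline.urine_series.index, window.start),
        hours_since(timeline.dialysis_events, window.start),
        np.array([T]),
    ]
    allt = np.concatenate([grid] + extra)
    allt = allt[(allt >= -1e-9) & (allt <= T + 1e-9)]
    return np.unique(np.round(allt, 9))


def stage_series(
    timeline: PatientTimeline,
    window: ObservationWindow,
    cfg: KDIGORuleConfig | None = None,
) -> DetectionResult:
    """Evaluate all three criteria on the full evaluation grid for one patient."""
    cfg = cfg or KDIGORuleConfig()
    origin = window.start
    t_eval = _evaluation_grid(timeline, window, cfg.eval_grid_step)
    n = len(t_eval)

    # urine criterion, vectorised over the whole grid
    acc = UrineAccrual.build(
        hours_since(timeline.urine_series.index, origin),
        timeline.urine_series.to_numpy(dtype=float),
        cfg.max_documentation_gap,
    )
    wfun = weight_interpolator(timeline.weight_series, origin, cfg.default_weight_kg)
    u_stage = np.zeros(n, dtype=int)
    u_rate = np.full(n, np.nan)
    u_window = np.zeros(n)
    if len(timeline.urine_series):
        for stage, w_h, thr in (
            (1, cfg.urine_window_stage1, cfg.urine_rate_low),
            (2, cfg.urine_window_stage2, cfg.urine_rate_low),
            (3, cfg.urine_window_stage3, cfg.urine_rate_verylow),
        ):
            rate, cov = _window_rates(acc, t_eval, w_h, wfun)
            hit = (~np.isnan(rate)) & (cov >= cfg.window_coverage_min) & (rate < thr)
            u_stage = np.where(hit, stage, u_stage)  # ascending loop: higher wins
            u_rate = np.where(hit, rate, u_rate)
            u_window = np.where(hit, w_h, u_window)

    # creatinine criterion at record times only
    c_stage = np.zeros(n, dtype=int)
    c_evidence: dict[int, dict] = {}
    creat = timeline.creatinine_series
    creat_in = creat[(creat.index >= window.start) & (creat.index <= window.end)]
    if len(creat_in):
        baseline = creatinine_baseline(creat, window)
        ct = hours_since(creat_in.index, origin)
        cv = creat_in.to_numpy(dtype=float)
        pos = {round(h, 9): i for i, h in enumerate(t_eval)}
        for j, (h, v) in enumerate(zip(ct, cv)):
            lo = bisect.bisect_right(ct, h - cfg.lookback_creat_min)
            delta = v - cv[lo : j + 1].min() if lo <= j else None
            s = creatinine_stage_value(v, baseline, delta, cfg)
            i = pos.get(round(h, 9))
            if i is not None and s > 0:
                c_stage[i] = s
                c_evidence[i] = {
                    "value": v,
                    "baseline": baseline,
                    "multiplier": v / baseline,
                    "delta_48h": delta,
                }

    # dialysis criterion persists from the first in-window event
    d_stage = np.zeros(n, dtype=int)
    ev_in = timeline.dialysis_events[
        (timeline.dialysis_events >= window.start)
        & (timeline.dialysis_events <= window.end)
    ]
    first_dialysis_h = None
    if len(ev_in):
        first_dialysis_h = float(hours_since(ev_in, origin)[0])
        d_stage[t_eval >= first_dialysis_h - 1e-9] = 3

    combined = np.maximum(np.maximum(u_stage, c_stage), d_stage)

    points: list[StagePoint] = []
    criterion_points: dict[str, list[StagePoint]] = {c: [] for c in ("urine", "creatinine", "dialysis")}
    for i in range(n):
        if combined[i] == 0:
            continue
        ts = origin + pd.Timedelta(hours=float(t_eval[i]))
        cands = []
        if d_stage[i]:
            p = StagePoint(ts, int(d_stage[i]), "dialysis", {"event_time_h": first_dialysis_h})
            criterion_points["dialysis"].append(p)
            cands.append(p)
        if u_stage[i]:
            p = StagePoint(
                ts,
                int(u_stage[i]),
                "urine",
                {"window_h": float(min(u_window[i], cfg.urine_window_cap)), "rate": float(u_rate[i])},
            )
            criterion_points["urine"].append(p)
            cands.append(p)
        if c_stage[i]:
            p = StagePoint(ts, int(c_stage[i]), "creatinine", c_evidence[i])
            criterion_points["creatinine"].append(p)
            cands.append(p)
        best = min(
            (p for p in cands if p.stage == combined[i]),
            key=lambda p: CRITERION_PRECEDENCE[p.criterion],
        )
        points.append(best)

    return DetectionResult(
        patient_id=timeline.patient_id,
        window=window,
        times_h=t_eval,
        stages=combined,
        cumulative=cumulative_max(combined),
        points=points,
        criterion_points=criterion_points,
    )


def cumulative_max(stages: np.ndarray) -> np.ndarray:
    """Running maximum of a time-ordered stage series."""
    if len(stages) == 0:
        return np.asarray(stages, dtype=int)
    return np.maximum.accumulate(np.asarray(stages, dtype=int))


def summarize(result: DetectionResult) -> AKISummary:
    """Collapse a detection result into the per-patient first/max summary."""
    if not result.points:
        s = AKISummary(
            patient_id=result.patient_id,
            has_aki=False,
            first_AKI_time=None,
            first_AKI_stage=None,
            max_AKI_time=None,
            max_AKI_stage=0,
        )
        s.validate()
        return s

    first = result.points[0]
    max_stage = max(p.stage for p in result.points)
    max_point = next(p for p in result.points if p.stage == max_stage)

    # criteria that ever indicated the max stage, and the earliest indication
    at_max: list[StagePoint] = []
    for crit, pts in result.criterion_points.items():
        hits = [p for p in pts if p.stage == max_stage]
        if hits:
            at_max.append(hits[0])
    at_max.sort(key=lambda p: (p.time, CRITERION_PRECEDENCE[p.criterion]))

    s = AKISummary(
        patient_id=result.patient_id,
        has_aki=True,
        first_AKI_time=first.time,
        first_AKI_stage=first.stage,
        max_AKI_time=max_point.time,
        max_AKI_stage=max_stage,
        criteria_at_max=frozenset(p.criterion for p in at_max),
        first_criterion_at_max=at_max[0].criterion,
        first_criterion_overall=first.criterion,
    )
    s.validate()
    return s


def detect_patient(
    timeline: PatientTimeline,
    cfg: KDIGORuleConfig | None = None,
) -> tuple[DetectionResult, AKISummary]:
    """Window derivation + staging + summary for one preprocessed patient."""
    from .preprocessing import derive_observation_window

    window = derive_observation_window(timeline)
    result = stage_series(timeline, window, cfg)
    return result, summarize(result)
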