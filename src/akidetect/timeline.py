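"""Core domain types: patient timelines, observation windows, stage assertions.

A :class:`PatientTimeline` bundles every timestamped signal exported from a
patient-data-management system (PDMS) for one de-identified ICU patient:
serum creatinine draws (mg/dl), urine-output charting records (ml accrued
since the previous record), body-weight records (kg), dialysis events, and
generic vital-sign timestamps used only to delimit the observation period.
Static fields (sex, age at admission, surgery type) ride along for cohort
analytics.

All timestamps are timezone-naive :class:`pandas.Timestamp` values on a
common clock; numeric series are :class:`pandas.Series` indexed by time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import PreconditionError

CRITERIA = ("urine", "creatinine", "dialysis")

#: tie-break precedence when several criteria indicate the same stage at the
#: same instant: dialysis > urine > creatinine
CRITERION_PRECEDENCE = {"dialysis": 0, "urine": 1, "creatinine": 2}

WEIGHT_BOUNDS_KG = (20.0, 400.0)


def _empty_series() -> pd.Series:
    return pd.Series([], index=pd.DatetimeIndex([]), dtype=float)


def _as_time_series(values) -> pd.Series:
    """Coerce (timestamp, value) pairs / dict / Series to a time-sorted Series."""
    if isinstance(values, pd.Series):
        s = values.copy()
    elif values is None or len(values) == 0:
        return _empty_series()
    else:
        ts, vs = zip(*values)
        s = pd.Series(list(vs), index=pd.DatetimeIndex(ts), dtype=float)
    s.index = pd.DatetimeIndex(s.index)
    return s.sort_index()


def _as_datetime_index(values) -> pd.DatetimeIndex:
    if values is None:
        return pd.DatetimeIndex([])
    return pd.DatetimeIndex(values).sort_values()


@dataclass
class PatientTimeline:
    """All signals and static fields for one de-identified patient."""

    patient_id: str
    sex: str = "unknown"  # {male, female, unknown}
    age_at_admission: Optional[int] = None  # completed years at ICU admission
    surgery_type: str = "cardiac"  # 'cardiac' or anything else
    weight_series: pd.Series = field(default_factory=_empty_series)
    creatinine_series: pd.Series = field(default_factory=_empty_series)
    urine_series: pd.Series = field(default_factory=_empty_series)
    dialysis_events: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([]))
    vital_timestamps: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([]))
    diagnosis_texts: list = field(default_factory=list)  # [(Timestamp|None, str)]
    drug_admins: list = field(default_factory=list)  # [(Timestamp, str)]

    def __post_init__(self) -> None:
        self.weight_series = _as_time_series(self.weight_series)
        self.creatinine_series = _as_time_series(self.creatinine_series)
        self.urine_series = _as_time_series(self.urine_series)
        self.dialysis_events = _as_datetime_index(self.dialysis_events)
        self.vital_timestamps = _as_datetime_index(self.vital_timestamps)

    def validate(self) -> None:
        """Raise :class:`PreconditionError` on any invariant violation."""
        for name, s in (
            ("weight", self.weight_series),
            ("creatinine", self.creatinine_series),
            ("urine", self.urine_series),
        ):
            if s.index.has_duplicates:
                raise PreconditionError(
                    f"{self.patient_id}: duplicate {name} timestamps"
                )
            if not s.index.is_monotonic_increasing:
                raise PreconditionError(
                    f"{self.patient_id}: {name} series not time-sorted"
                )
        if (self.creatinine_series <= 0).any():
            raise PreconditionError(f"{self.patient_id}: non-positive creatinine")
        if (self.urine_series < 0).any():
            raise PreconditionError(f"{self.patient_id}: negative urine volume")
        lo, hi = WEIGHT_BOUNDS_KG
        w = self.weight_series
        if len(w) and ((w <= lo) | (w >= hi)).any():
            raise PreconditionError(f"{self.patient_id}: implausible body weight")

    @property
    def all_signal_times(self) -> pd.DatetimeIndex:
        """Union of every dynamic-signal timestamp (vitals, labs, urine, weight, dialysis)."""
        parts = [
            self.vital_timestamps,
            self.creatinine_series.index,
            self.urine_series.index,
            self.weight_series.index,
            self.dialysis_events,
        ]
        out = pd.DatetimeIndex([])
        for p in parts:
            out = out.union(p)
        return out


@dataclass(frozen=True)
class ObservationWindow:
    """Per-patient analysis span: first ICU signal to last signal, capped at 14 days."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PreconditionError("observation window start must precede end")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    @property
    def duration_days(self) -> float:
        return self.duration_hours / 24.0

    def contains(self, t: pd.Timestamp) -> bool:
        return self.start <= t <= self.end


@dataclass(frozen=True)
class StagePoint:
    """One timestamped stage assertion by a single criterion (or combined)."""

    time: pd.Timestamp
    stage: int  # 1, 2 or 3
    criterion: str  # urine | creatinine | dialysis
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise PreconditionError(f"stage must be 1..3, got {self.stage}")
        if self.criterion not in CRITERIA:
            raise PreconditionError(f"unknown criterion {self.criterion!r}")


@dataclass
class AKISummary:
    """Per-patient first/max detection summary.

    ``first_AKI_*`` describe the earliest detection of any stage;
    ``max_AKI_stage`` is the highest stage ever indicated and
    ``max_AKI_time`` the earliest instant it was reached.
    """

    patient_id: str
    has_aki: bool
    first_AKI_time: Optional[pd.Timestamp]
    first_AKI_stage: Optional[int]
    max_AKI_time: Optional[pd.Timestamp]
    max_AKI_stage: int
    criteria_at_max: frozenset = frozenset()
    first_criterion_at_max: Optional[str] = None
    first_criterion_overall: Optional[str] = None

    def validate(self) -> None:
        if self.has_aki != (self.max_AKI_stage >= 1):
            raise PreconditionError("has_aki must match max_AKI_stage >= 1")
        if self.has_aki:
            if self.first_AKI_time is None or self.max_AKI_time is None:
                raise PreconditionError("AKI summaries need first/max times")
            if self.first_AKI_time > self.max_AKI_time:
                raise PreconditionError("first_AKI_time must not exceed max_AKI_time")
            if self.first_AKI_stage is None or self.first_AKI_stage > self.max_AKI_stage:
                raise PreconditionError("first_AKI_stage must not exceed max_AKI_stage")
            if not self.criteria_at_max:
                raise PreconditionError("criteria_at_max empty despite AKI")
        else:
            if self.max_AKI_stage != 0:
                raise PreconditionError("no-AKI summary must have stage 0")


def hours_since(index, origin: pd.Timestamp) -> np.ndarray:
    """Timestamps -> float hours since ``origin`` (vectorised)."""
    idx = pd.DatetimeIndex(index)
    return (idx - origin) / pd.Timedelta(hours=1)
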