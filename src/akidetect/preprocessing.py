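"""Cohort preprocessing: exclusion cascade, observation windows, weight interpolation.

Exclusion mirrors the three-step screening used when constructing a
cardiac-surgery ICU cohort from PDMS exports:

1. ``non_cardiac_surgery`` — surgery type other than heart-related;
2. ``missing_or_invalid_data`` — no usable sex, implausible age, or no body
   weight (and no configured fallback weight) so urine output cannot be
   normalised;
3. ``improper_data_for_use`` — dialysis already running before the first ICU
   signal, no vital timestamps to anchor the observation period, or too few
   AKI-relevant signals to evaluate any criterion.

A patient failing several rules is attributed to the *first* matching rule in
this fixed order, which keeps the accounting deterministic and conservative
(screened == included + sum of per-rule exclusions).

The observation period of an included patient starts at the first available
vital-sign timestamp and runs to the last signal of any kind, capped at 14
days — exact ICU admission/discharge times are generally not reconstructible
from archived PDMS data, so the signal span is used as the stay proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .timeline import ObservationWindow, PatientTimeline, hours_since

RULE_NON_CARDIAC = "non_cardiac_surgery"
RULE_MISSING = "missing_or_invalid_data"
RULE_IMPROPER = "improper_data_for_use"
RULES = (RULE_NON_CARDIAC, RULE_MISSING, RULE_IMPROPER)

MAX_WINDOW_DAYS = 14.0


@dataclass
class ExclusionConfig:
    """Operational parameters of the screening cascade."""

    age_min: int = 18
    age_max: int = 110
    min_creatinine_records: int = 1
    min_urine_records: int = 2
    default_weight_kg: Optional[float] = None  # fallback when no weight charted
    require_cardiac: bool = True


@dataclass
class ExclusionLog:
    """Screening tallies; ``screened == included + sum(excluded.values())``."""

    screened: int = 0
    included: int = 0
    excluded: dict = field(
        default_factory=lambda: {r: 0 for r in RULES}
    )
    #: per-patient attribution, id -> rule (diagnostic, not part of the tally contract)
    attribution: dict = field(default_factory=dict)

    def check(self) -> None:
        if self.screened != self.included + sum(self.excluded.values()):
            raise PreconditionError("exclusion log does not conserve patients")

    def to_frame(self) -> pd.DataFrame:
        rows = [("screened", self.screened), ("included", self.included)]
        rows += [(f"excluded_{r}", n) for r, n in self.excluded.items()]
        return pd.DataFrame(rows, columns=["rule", "count"])


def _exclusion_rule(t: PatientTimeline, cfg: ExclusionConfig) -> Optional[str]:
    """First matching exclusion rule for one patient, or None if includable."""
    if cfg.require_cardiac and t.surgery_type != "cardiac":
        return RULE_NON_CARDIAC
    if t.sex not in ("male", "female"):
        return RULE_MISSING
    if t.age_at_admission is None or not (cfg.age_min <= t.age_at_admission <= cfg.age_max):
        return RULE_MISSING
    if len(t.weight_series) == 0 and cfg.default_weight_kg is None:
        return RULE_MISSING
    if len(t.vital_timestamps) == 0:
        return RULE_IMPROPER
    first_vital = t.vital_timestamps[0]
    if len(t.dialysis_events) and t.dialysis_events[0] < first_vital:
        return RULE_IMPROPER  # dialysis before ICU
    if len(t.creatinine_series) < cfg.min_creatinine_records:
        return RULE_IMPROPER  # insufficient AKI signals
    if len(t.urine_series) < cfg.min_urine_records:
        return RULE_IMPROPER
    try:
        derive_observation_window(t)
    except PreconditionError:
        return RULE_IMPROPER  # degenerate signal span: unclear case
    return None


def apply_exclusions(
    raw: Iterable[PatientTimeline], cfg: ExclusionConfig | None = None
) -> tuple[list[PatientTimeline], ExclusionLog]:
    """Screen raw timelines; return the included cohort and the exclusion log."""
    cfg = cfg or ExclusionConfig()
    log = ExclusionLog()
    cohort: list[PatientTimeline] = []
    for t in raw:
        log.screened += 1
        rule = _exclusion_rule(t, cfg)
        if rule is None:
            cohort.append(t)
            log.included += 1
        else:
            log.excluded[rule] += 1
            log.attribution[t.patient_id] = rule
    log.check()
    return cohort, log


def derive_observation_window(t: PatientTimeline) -> ObservationWindow:
    """Observation span: first vital timestamp to last signal, capped at 14 days."""
    if len(t.vital_timestamps) == 0:
        raise PreconditionError(f"{t.patient_id}: no vital timestamps")
    start = t.vital_timestamps[0]
    last_signal = t.all_signal_times.max()
    end = min(last_signal, start + pd.Timedelta(days=MAX_WINDOW_DAYS))
    if not start < end:
        raise PreconditionError(f"{t.patient_id}: degenerate observation window")
    return ObservationWindow(start=start, end=end)


def interpolate_weight(
    weights: pd.Series, t, default_weight_kg: Optional[float] = None
):
    """Body weight (kg) at time(s) ``t``: linear between records, constant beyond.

    ``t`` may be a single timestamp or an array of float hours paired with a
    ``origin`` via :func:`weight_interpolator`; this convenience form takes
    timestamps only.
    """
    if len(weights) == 0:
        if default_weight_kg is not None:
            return default_weight_kg
        raise PreconditionError("no weight records and no default weight")
    weights = weights.sort_index()
    origin = weights.index[0]
    xp = hours_since(weights.index, origin)
    single = isinstance(t, pd.Timestamp)
    tq = pd.DatetimeIndex([t]) if single else pd.DatetimeIndex(t)
    x = hours_since(tq, origin)
    out = np.interp(x, xp, weights.to_numpy(dtype=float))
    return float(out[0]) if single else out


def weight_interpolator(
    weights: pd.Series, origin: pd.Timestamp, default_weight_kg: Optional[float] = None
):
    """Return ``f(hours_since_origin) -> kg`` for fast repeated evaluation."""
    if len(weights) == 0:
        if default_weight_kg is None:
            raise PreconditionError("no weight records and no default weight")
        return lambda h: np.full_like(np.asarray(h, dtype=float), default_weight_kg)
    weights = weights.sort_index()
    xp = hours_since(weights.index, origin)
    fp = weights.to_numpy(dtype=float)
    return lambda h: np.interp(np.asarray(h, dtype=float), xp, fp)
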