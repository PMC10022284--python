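"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from akidetect.timeline import PatientTimeline

T0 = pd.Timestamp("2024-01-01 06:00:00")


def ts(hours):
    """Float hours since T0 -> DatetimeIndex."""
    return pd.DatetimeIndex(
        T0 + pd.to_timedelta(np.asarray(hours, dtype=float), unit="h")
    )


def make_timeline(
    pid: str = "p1",
    *,
    sex: str = "male",
    age: int = 65,
    surgery: str = "cardiac",
    creat=(),  # [(hour, mg/dl)]
    urine=(),  # [(hour, ml)]
    weights=((0.0, 80.0),),
    dialysis=(),  # [hour]
    vitals_span_h: float | None = None,
    vitals=None,  # explicit hours, overrides span
    diagnoses=(),
    drugs=(),
) -> PatientTimeline:
    """Convenience builder with hour offsets from a fixed origin."""
    if vitals is None:
        span = vitals_span_h
        if span is None:
            cands = [h for h, _ in list(creat) + list(urine) + list(weights)]
            cands += list(dialysis)
            span = max(cands) if cands else 24.0
        vitals = np.arange(0.0, span + 1e-9, 1.0)
    return PatientTimeline(
        patient_id=pid,
        sex=sex,
        age_at_admission=age,
        surgery_type=surgery,
        creatinine_series=[(ts([h])[0], v) for h, v in creat],
        urine_series=[(ts([h])[0], v) for h, v in urine],
        weight_series=[(ts([h])[0], v) for h, v in weights],
        dialysis_events=list(ts(list(dialysis))),
        vital_timestamps=list(ts(vitals)),
        diagnosis_texts=[(ts([h])[0] if h is not None else None, x) for h, x in diagnoses],
        drug_admins=[(ts([h])[0], d) for h, d in drugs],
    )


def hourly_urine(rates_per_hour, weight_kg: float = 80.0):
    """Records for hourly charting: hour i+1 carries rate[i]*weight ml."""
    return [
        (float(i + 1), float(r) * weight_kg) for i, r in enumerate(rates_per_hour)
    ]


def brute_force_urine_rate(
    record_hours, volumes, t_end_h, window_h, weight_kg, resolution_min: int = 1
):
    """Independent 1-minute discretised allocator for window-average urine rate.

    Each record's volume is spread uniformly over the minutes of its accrual
    interval (previous record -> record; the first record accrues from hour
    0); the rate is the sum of minute-volumes inside the window divided by
    weight times window length.
    """
    total = 0.0
    prev = 0.0
    # inputs sit on the minute grid: work in exact integer minutes
    a = int(round((t_end_h - window_h) * 60.0))
    b = int(round(t_end_h * 60.0))
    for t, v in zip(record_hours, volumes):
        lo, hi = int(round(prev * 60.0)), int(round(t * 60.0))
        n_min = hi - lo
        if n_min <= 0:
            prev = t
            continue
        per_min = v / n_min
        for m in range(lo, hi):
            if m >= a and m + 1 <= b:
                total += per_min
        prev = t
    return total / (weight_kg * window_h)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
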