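"""Synthetic PDMS-style cohort generator with analytic ground truth.

Each generated patient carries a noise-free *planted* physiological signal —
a piecewise-constant diuresis rate (ml/kg/h), a piecewise-linear serum
creatinine curve (mg/dl) and an optional dialysis event — from which the
charted records are derived. AKI episodes are planted as:

* **urine mechanism** — an oliguria segment at a sub-threshold rate
  (0.45 ml/kg/h for stage 1, 0.40 for stage 2, 0.20 for stage 3) of a
  duration calibrated so the trailing-window-average rules reach exactly the
  planted stage and no higher;
* **creatinine mechanism** — a linear ramp from the per-patient baseline to
  a peak inside the target multiplier band, followed by a plateau;
* **dialysis mechanism** — a dialysis event (stage 3 by definition).

The first time each staging rule is met is derived *in closed form* from the
planted signal (piecewise-linear window totals for urine, ramp crossings for
creatinine), never by running the detector — so detector tests against this
ground truth are non-circular.

Realism knobs follow the charting statistics of cardiac-surgery ICU
documentation: about 10.6 urine records per patient-day with inter-record
gaps almost always below 4.5 h, sparse creatinine draws, daily weights,
14-day-capped stays with a median around 7.8 days, and AKI documented in
free text for only a small fraction of true episodes. Measurement noise is
*truncated* (at about two scale units) so that planted stages are exact:
noise can never push a patient across a staging threshold by itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pdms_io import write_cohort_tables
from .timeline import PatientTimeline

EPOCH = pd.Timestamp("2022-01-01 08:00:00")

#: German free-text phrases for comorbidity sampling (all map to a known code)
COMORBIDITY_PHRASES = [
    ("chronische ischämische Herzkrankheit", "I25"),
    ("essentielle Hypertonie", "I10"),
    ("Hyperlipidämie", "E78"),
    ("Diabetes mellitus Typ 2", "E14"),
    ("Aortenklappenstenose", "I35"),
    ("Mitralklappeninsuffizienz", "I34"),
    ("Vorhofflimmern", "I48"),
    ("chronische Niereninsuffizienz", "N18"),
    ("Adipositas", "E66"),
    ("Atherosklerose", "I70"),
    ("COPD", "J44"),
    ("Schlafapnoe", "G47"),
    ("akute Endokarditis", "I33"),
    ("Aortenaneurysma", "I71"),
]

DRUG_POOL = [
    "Furosemid", "Metoprolol", "Amiodaron", "Noradrenalin", "Propofol",
    "Heparin", "Pantoprazol", "Insulin", "Paracetamol", "Morphin",
    "Cefuroxim", "Simvastatin", "Ramipril", "Amlodipin", "Digoxin",
]
NEPHROTOXIC_POOL = ["Ibuprofen", "Vancomycin"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort."""

    n_patients: int = 100
    seed: int = 0
    #: probability of max stage 0 / 1 / 2 / 3
    stage_mix: tuple = (0.346, 0.176, 0.305, 0.173)
    #: P(mechanism | AKI): urine / creatinine / dialysis (dialysis => stage 3)
    mechanism_mix: tuple = (0.70, 0.25, 0.05)
    #: probability of a secondary creatinine ramp to the same stage
    secondary_creatinine_prob: float = 0.30
    urine_records_per_day: float = 10.6
    urine_gap_shape: float = 4.0  # gamma shape; scale fixed by the mean gap
    #: mean charting gap during oliguria — urine monitoring intensifies to
    #: roughly hourly once output drops, and the rate change itself is charted
    oliguria_gap_mean_h: float = 1.0
    creatinine_draw_interval_h: float = 12.0
    creatinine_draw_jitter_h: float = 3.0
    weight_noise_kg: float = 0.4
    urine_noise_sigma: float = 0.2  # log-scale, truncated at 1.8 sigma
    creatinine_noise_sigma: float = 0.02  # relative, truncated at 2 sigma
    documentation_dropout: float = 0.02
    documented_aki_prob: float = 0.0275  # P(explicit AKI diagnosis | true AKI)
    decoy_prob: float = 0.08  # P(adding an 'Aortenklappeninsuffizienz' text)
    stay_median_days: float = 7.8
    stay_log_sigma: float = 0.527  # matches an IQR of roughly (5.8, 11.8)
    stay_cap_days: float = 14.0
    comorbidity_mean: float = 1.8
    drugs_mean: float = 18.0
    nephrotoxic_prob: float = 0.065
    #: fractions of deliberately non-includable patients
    frac_non_cardiac: float = 0.0
    frac_missing_sex: float = 0.0
    frac_pre_icu_dialysis: float = 0.0
    #: 'irregular' (gamma gaps, sparse labs) or 'hourly' (gapless charting)
    charting: str = "irregular"

    def validate(self) -> None:
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.stage_mix):
            raise ConfigurationError("stage_mix must be a probability vector")
        if abs(sum(self.mechanism_mix) - 1.0) > 1e-9:
            raise ConfigurationError("mechanism_mix must sum to 1")
        for name in ("urine_records_per_day", "stay_median_days", "stay_cap_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "documentation_dropout", "documented_aki_prob", "decoy_prob",
            "nephrotoxic_prob", "frac_non_cardiac", "frac_missing_sex",
            "frac_pre_icu_dialysis", "secondary_creatinine_prob",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.charting not in ("irregular", "hourly"):
            raise ConfigurationError("charting must be 'irregular' or 'hourly'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown simulate config keys: {sorted(unknown)}")
        for k in ("stage_mix", "mechanism_mix"):
            if k in known:
                known[k] = tuple(known[k])
        cfg = cls(**known)
        cfg.validate()
        return cfg


@dataclass
class GroundTruthEpisode:
    """Planted truth for one patient: max stage and analytic rule-satisfaction times."""

    patient_id: str
    planted_stage: int
    mechanisms: list  # e.g. ["urine"], ["urine", "creatinine"]
    #: non-decreasing trajectory: (stage, first-satisfaction hour, mechanism)
    trajectory: list = field(default_factory=list)
    expected_exclusion: Optional[str] = None
    documented_aki: bool = False

    @property
    def stage_times_h(self) -> dict:
        return {s: t for s, t, _ in self.trajectory}


# ---------------------------------------------------------------------------
# analytic rule-satisfaction times
# ---------------------------------------------------------------------------

def first_window_avg_below(
    segments: list, window_h: float, threshold: float, t_max: float
) -> Optional[float]:
    """Earliest t with mean of a piecewise-constant rate over [t-w, t] < threshold.

    ``segments`` is a contiguous list of ``(start, end, rate)`` covering
    ``[0, t_max]``. Only times with the full window inside the observation
    span (t >= w) qualify. Returns the crossing time, or None. The crossing
    is where the average *reaches* the threshold; a strict-inequality rule is
    met immediately after.
    """
    knots = [segments[0][0]]
    cum = [0.0]
    for a, b, r in segments:
        knots.append(b)
        cum.append(cum[-1] + r * (b - a))
    knots = np.asarray(knots)
    cum = np.asarray(cum)

    def R(t):
        return np.interp(t, knots, cum)

    brk = np.unique(
        np.concatenate([knots, knots + window_h, [window_h, t_max]])
    )
    brk = brk[(brk >= window_h) & (brk <= t_max)]
    if len(brk) == 0:
        return None
    target = threshold * window_h
    g = R(brk) - R(brk - window_h)
    if g[0] < target:
        return float(brk[0])
    for i in range(1, len(g)):
        if g[i] < target:  # g is linear on [brk[i-1], brk[i]]
            a, b = brk[i - 1], brk[i]
            ga, gb = g[i - 1], g[i]
            return float(a + (ga - target) / (ga - gb) * (b - a))
    return None


def ramp_crossing(
    baseline: float, peak: float, on_h: float, dur_h: float, level: float
) -> Optional[float]:
    """Time a linear ramp from baseline (at on_h) to peak (at on_h+dur_h) reaches level."""
    if peak < level or peak <= baseline:
        return None
    if level <= baseline:
        return on_h
    return on_h + dur_h * (level - baseline) / (peak - baseline)


# ---------------------------------------------------------------------------
# planted signal models
# ---------------------------------------------------------------------------

@dataclass
class _PlantedSignals:
    stay_h: float
    weight_kg: float
    base_rate: float  # normal diuresis, ml/kg/h
    oliguria: Optional[tuple] = None  # (on_h, off_h, rate)
    creat_baseline: float = 0.9
    creat_ramp: Optional[tuple] = None  # (on_h, dur_h, peak) then plateau to stay end
    dialysis_h: Optional[float] = None

    def rate_segments(self) -> list:
        """Contiguous (start, end, rate) partition of [0, stay_h]."""
        if self.oliguria is None:
            return [(0.0, self.stay_h, self.base_rate)]
        on, off, r = self.oliguria
        segs = []
        if on > 0:
            segs.append((0.0, on, self.base_rate))
        segs.append((on, off, r))
        if off < self.stay_h:
            segs.append((off, self.stay_h, self.base_rate))
        return segs

    def rate_integral(self, a: float, b: float) -> float:
        """∫ rate dt over [a, b] of the noise-free planted rate (ml/kg)."""
        total = 0.0
        for s, e, r in self.rate_segments():
            total += r * max(0.0, min(b, e) - max(a, s))
        return total

    def in_oliguria(self, a: float, b: float) -> float:
        if self.oliguria is None:
            return 0.0
        on, off, _ = self.oliguria
        return max(0.0, min(b, off) - max(a, on))

    def creatinine(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = np.full_like(t, self.creat_baseline)
        if self.creat_ramp is not None:
            on, dur, peak = self.creat_ramp
            frac = np.clip((t - on) / dur, 0.0, 1.0)
            c = self.creat_baseline + frac * (peak - self.creat_baseline)
            c[t < on] = self.creat_baseline
        return c


def _truth_trajectory(sig: _PlantedSignals, planted_stage: int) -> list:
    """Closed-form first-satisfaction times for every stage the signals imply."""
    per_stage: dict[int, tuple] = {}

    def offer(stage: int, t: Optional[float], mech: str) -> None:
        if t is None or t > sig.stay_h:
            return
        if stage not in per_stage or t < per_stage[stage][0]:
            per_stage[stage] = (t, mech)

    segs = sig.rate_segments()
    offer(1, first_window_avg_below(segs, 6.0, 0.5, sig.stay_h), "urine")
    offer(2, first_window_avg_below(segs, 12.0, 0.5, sig.stay_h), "urine")
    offer(3, first_window_avg_below(segs, 24.0, 0.3, sig.stay_h), "urine")

    if sig.creat_ramp is not None:
        on, dur, peak = sig.creat_ramp
        b = sig.creat_baseline
        # stage 1: multiplier 1.5 or +0.3 mg/dl over the 48 h rolling minimum
        offer(1, ramp_crossing(b, peak, on, dur, min(1.5 * b, b + 0.3)), "creatinine")
        offer(2, ramp_crossing(b, peak, on, dur, 2.0 * b), "creatinine")
        offer(3, ramp_crossing(b, peak, on, dur, min(3.0 * b, 4.0)), "creatinine")

    if sig.dialysis_h is not None:
        offer(3, sig.dialysis_h, "dialysis")

    traj = [(s, t, m) for s, (t, m) in sorted(per_stage.items())]
    # sanity: the signals must realise exactly the planted maximum
    got = max((s for s, _, _ in traj), default=0)
    if got != planted_stage:
        raise ConfigurationError(
            f"planted signals realise stage {got}, expected {planted_stage}"
        )
    return traj


# ---------------------------------------------------------------------------
# episode planting
# ---------------------------------------------------------------------------

#: planted oliguria rate and duration range (h) per target stage; durations
#: are calibrated so the next-higher window rule can never fire, even at the
#: truncated-noise floor of the surrounding normal diuresis
_OLIGURIA_PLAN = {1: (0.45, (7.0, 9.0)), 2: (0.40, (13.0, 20.0)), 3: (0.20, (26.0, 40.0))}

#: creatinine peak multiplier band per target stage; kept inside the staging
#: band with margin for the truncated *relative* measurement noise, which
#: rescales every observed multiplier by up to (1+2σ)/(1-2σ) because the
#: baseline itself is a noisy draw
_CREAT_PEAK_BAND = {1: (1.60, 1.80), 2: (2.20, 2.60), 3: (3.30, 3.90)}


def _plan_episode(
    rng: np.random.Generator, cfg: SimulationConfig, stage: int, stay_h: float,
    sig: _PlantedSignals,
) -> list:
    """Attach planted mechanisms for the drawn max stage; returns mechanism list."""
    if stage == 0:
        return []
    mech = rng.choice(("urine", "creatinine", "dialysis"), p=cfg.mechanism_mix)
    if mech == "dialysis" and stage != 3:
        mech = "urine"
    mechanisms = [mech]

    if mech == "urine":
        rate, (dlo, dhi) = _OLIGURIA_PLAN[stage]
        dur = float(np.round(rng.uniform(dlo, dhi)))
        on = float(np.round(rng.uniform(4.0, max(5.0, stay_h - dur - 4.0))))
        sig.oliguria = (on, on + dur, rate)
    elif mech == "creatinine":
        lo, hi = _CREAT_PEAK_BAND[stage]
        peak = sig.creat_baseline * rng.uniform(lo, hi)
        dur = rng.uniform(18.0, 30.0)
        on = rng.uniform(6.0, max(7.0, stay_h - dur - 20.0))
        sig.creat_ramp = (on, dur, peak)
    else:  # dialysis
        sig.dialysis_h = float(np.round(rng.uniform(12.0, stay_h - 2.0)))
        # dialysis patients usually oligo-anuric beforehand
        if rng.random() < 0.5:
            rate, (dlo, dhi) = _OLIGURIA_PLAN[2]
            dur = float(np.round(rng.uniform(dlo, dhi)))
            on = max(4.0, sig.dialysis_h - dur)
            sig.oliguria = (on, on + dur, rate)
            mechanisms.append("urine")

    if (
        mech == "urine"
        and cfg.secondary_creatinine_prob > 0
        and rng.random() < cfg.secondary_creatinine_prob
    ):
        lo, hi = _CREAT_PEAK_BAND[stage]
        peak = sig.creat_baseline * rng.uniform(lo, hi)
        dur = rng.uniform(18.0, 30.0)
        latest = stay_h - dur - 20.0
        if latest > 6.0:
            sig.creat_ramp = (rng.uniform(6.0, latest), dur, peak)
            mechanisms.append("creatinine")
    return mechanisms


# ---------------------------------------------------------------------------
# record synthesis
# ---------------------------------------------------------------------------

def _truncated_normal(rng, sigma: float, size, trunc: float = 2.0):
    return np.clip(rng.normal(0.0, sigma, size), -trunc * sigma, trunc * sigma)


def _urine_times(
    rng, cfg: SimulationConfig, stay_h: float, oliguria: Optional[tuple] = None
) -> np.ndarray:
    """Charting times: gamma gaps, intensified to ~hourly during oliguria.

    A record is placed at each oliguria boundary — in practice the nurse
    charts the bag when output visibly changes, and monitoring tightens to
    an hourly rhythm while output is low.
    """
    if cfg.charting == "hourly":
        return np.arange(1.0, stay_h + 1e-9, 1.0)
    base_gap = 24.0 / cfg.urine_records_per_day
    on, off = (oliguria[0], oliguria[1]) if oliguria is not None else (np.inf, np.inf)
    times = []
    t = 0.0
    while True:
        mean = cfg.oliguria_gap_mean_h if on <= t < off else base_gap
        nxt = t + rng.gamma(cfg.urine_gap_shape, mean / cfg.urine_gap_shape)
        for boundary in (on, off):
            if t < boundary < nxt:
                nxt = boundary
                break
        if nxt > stay_h:
            break
        times.append(nxt)
        t = nxt
    return np.asarray(times)


def _creatinine_times(rng, cfg: SimulationConfig, stay_h: float) -> np.ndarray:
    if cfg.charting == "hourly":
        return np.arange(0.0, stay_h + 1e-9, 1.0)
    base = np.arange(1.0, stay_h, cfg.creatinine_draw_interval_h)
    jitter = rng.uniform(-cfg.creatinine_draw_jitter_h, cfg.creatinine_draw_jitter_h, len(base))
    t = np.clip(base + jitter, 0.0, stay_h)
    return np.unique(np.round(t, 3))


def generate_patient(
    cfg: SimulationConfig, rng: np.random.Generator, patient_id: str = "p0"
) -> tuple[PatientTimeline, GroundTruthEpisode]:
    """One synthetic patient with analytic ground truth."""
    cfg.validate()
    stage = int(rng.choice(4, p=cfg.stage_mix))
    stay_d = float(
        min(cfg.stay_cap_days, np.exp(rng.normal(np.log(cfg.stay_median_days), cfg.stay_log_sigma)))
    )
    stay_d = max(stay_d, 1.5)
    if stage > 0 and stay_d < 3.0:
        # planted episodes need room for their windows; short stays are bumped
        stay_d = 3.0 + rng.uniform(0.0, 1.0)
    stay_h = stay_d * 24.0

    sig = _PlantedSignals(
        stay_h=stay_h,
        weight_kg=float(np.clip(rng.normal(82.0, 14.0), 48.0, 150.0)),
        base_rate=float(rng.uniform(1.0, 1.4)),
        creat_baseline=float(rng.uniform(0.7, 1.3)),
    )
    mechanisms = _plan_episode(rng, cfg, stage, stay_h, sig)
    trajectory = _truth_trajectory(sig, stage)

    start = EPOCH + pd.Timedelta(days=float(rng.integers(0, 3000)))

    def ts(hours):
        return pd.DatetimeIndex(start + pd.to_timedelta(np.asarray(hours, dtype=float), unit="h"))

    vitals = np.arange(0.0, stay_h + 1e-9, 1.0)

    w_times = np.arange(1.0, stay_h, 24.0)
    w_noise = _truncated_normal(rng, cfg.weight_noise_kg, len(w_times))
    weights = list(zip(ts(w_times), sig.weight_kg + w_noise))

    u_times = _urine_times(rng, cfg, stay_h, sig.oliguria)
    u_vols = []
    prev = 0.0
    for t in u_times:
        olig_overlap = sig.in_oliguria(prev, t)
        base_vol = sig.base_rate * ((t - prev) - olig_overlap)
        olig_vol = sig.rate_integral(prev, t) - base_vol
        if cfg.urine_noise_sigma > 0:
            f = float(
                np.exp(np.clip(rng.normal(0.0, cfg.urine_noise_sigma), -1.8 * cfg.urine_noise_sigma, 1.8 * cfg.urine_noise_sigma))
            )
        else:
            f = 1.0
        u_vols.append((base_vol * f + olig_vol) * sig.weight_kg)
        prev = t
    urine = list(zip(ts(u_times), u_vols))

    c_times = _creatinine_times(rng, cfg, stay_h)
    c_vals = sig.creatinine(c_times)
    if cfg.creatinine_noise_sigma > 0:
        c_vals = c_vals * (1.0 + _truncated_normal(rng, cfg.creatinine_noise_sigma, len(c_times)))
    creatinine = list(zip(ts(c_times), np.maximum(c_vals, 0.05)))

    dialysis = [] if sig.dialysis_h is None else list(ts([sig.dialysis_h]))

    diagnoses = []
    n_com = int(rng.poisson(cfg.comorbidity_mean))
    for k in rng.choice(len(COMORBIDITY_PHRASES), size=min(n_com, len(COMORBIDITY_PHRASES)), replace=False):
        diagnoses.append((start, COMORBIDITY_PHRASES[int(k)][0]))
    if rng.random() < cfg.decoy_prob:
        diagnoses.append((start, "AKI (Aortenklappeninsuffizienz)"))
    documented = False
    if stage > 0 and rng.random() < cfg.documented_aki_prob:
        t_doc = trajectory[-1][1] + rng.uniform(2.0, 24.0)
        diagnoses.append((start + pd.Timedelta(hours=min(t_doc, stay_h)), "akutes Nierenversagen"))
        documented = True

    drugs = []
    n_drugs = max(1, int(rng.poisson(cfg.drugs_mean)))
    for k in range(n_drugs):
        name = DRUG_POOL[int(rng.integers(0, len(DRUG_POOL)))]
        drugs.append((start + pd.Timedelta(hours=float(rng.uniform(0, stay_h))), name))
    if rng.random() < cfg.nephrotoxic_prob:
        name = NEPHROTOXIC_POOL[int(rng.integers(0, len(NEPHROTOXIC_POOL)))]
        for _ in range(int(rng.integers(1, 3))):
            drugs.append((start + pd.Timedelta(hours=float(rng.uniform(0, stay_h))), name))
    drugs.sort(key=lambda kv: kv[0])

    timeline = PatientTimeline(
        patient_id=patient_id,
        sex="male" if rng.random() < 0.715 else "female",
        age_at_admission=int(np.clip(rng.normal(70.0, 11.0), 20, 95)),
        surgery_type="cardiac",
        weight_series=weights,
        creatinine_series=creatinine,
        urine_series=urine,
        dialysis_events=dialysis,
        vital_timestamps=list(ts(vitals)),
        diagnosis_texts=diagnoses,
        drug_admins=drugs,
    )
    truth = GroundTruthEpisode(
        patient_id=patient_id,
        planted_stage=stage,
        mechanisms=mechanisms,
        trajectory=trajectory,
        documented_aki=documented,
    )
    return timeline, truth


def degrade_documentation(
    timeline: PatientTimeline, cfg: SimulationConfig, rng: np.random.Generator
) -> PatientTimeline:
    """Drop charting records at the configured rate; ground truth unchanged.

    A dropped urine record merges its accrued volume into the following
    record (the catheter bag keeps filling; the next charting catches up);
    a dropped trailing record loses its volume. Creatinine draws are simply
    lost.
    """
    t = timeline
    if cfg.documentation_dropout <= 0:
        return t
    p = cfg.documentation_dropout

    urine = t.urine_series
    if len(urine):
        keep = rng.random(len(urine)) >= p
        vols = urine.to_numpy(dtype=float).copy()
        carry = 0.0
        out_vols = []
        for i in range(len(vols)):
            if keep[i]:
                out_vols.append(vols[i] + carry)
                carry = 0.0
            else:
                carry += vols[i]
        urine = pd.Series(out_vols, index=urine.index[keep])

    creat = t.creatinine_series
    if len(creat):
        keep_c = rng.random(len(creat)) >= p
        if not keep_c.any():
            keep_c[0] = True  # never lose the baseline draw entirely
        creat = creat[keep_c]

    return PatientTimeline(
        patient_id=t.patient_id,
        sex=t.sex,
        age_at_admission=t.age_at_admission,
        surgery_type=t.surgery_type,
        weight_series=t.weight_series,
        creatinine_series=creat,
        urine_series=urine,
        dialysis_events=t.dialysis_events,
        vital_timestamps=t.vital_timestamps,
        diagnosis_texts=list(t.diagnosis_texts),
        drug_admins=list(t.drug_admins),
    )


def _plant_exclusion(
    timeline: PatientTimeline, rule: str
) -> PatientTimeline:
    if rule == "non_cardiac_surgery":
        timeline.surgery_type = "abdominal"
    elif rule == "missing_or_invalid_data":
        timeline.sex = "unknown"
    elif rule == "improper_data_for_use":
        first = timeline.vital_timestamps[0]
        ev = timeline.dialysis_events.union(
            pd.DatetimeIndex([first - pd.Timedelta(hours=6)])
        )
        timeline.dialysis_events = ev
    return timeline


def generate_cohort(
    cfg: SimulationConfig, outdir=None
) -> tuple[list[PatientTimeline], list[GroundTruthEpisode]]:
    """Generate ``cfg.n_patients`` patients with independent per-patient sub-seeds.

    A configurable fraction violates the inclusion rules (non-cardiac
    surgery, missing sex, dialysis before the first ICU signal) to exercise
    preprocessing. When ``outdir`` is given, the cohort is written in the
    canonical table layout plus a ground-truth manifest (CSV and JSON).
    """
    cfg.validate()
    timelines, truths = [], []
    excl_plan = (
        [("non_cardiac_surgery", cfg.frac_non_cardiac),
         ("missing_or_invalid_data", cfg.frac_missing_sex),
         ("improper_data_for_use", cfg.frac_pre_icu_dialysis)]
    )
    master = np.random.default_rng(cfg.seed)
    excl_draw = master.random(cfg.n_patients)
    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:05d}"
        t, truth = generate_patient(cfg, rng, pid)
        t = degrade_documentation(t, cfg, rng)
        x = excl_draw[i]
        acc = 0.0
        for rule, frac in excl_plan:
            acc += frac
            if x < acc:
                t = _plant_exclusion(t, rule)
                truth.expected_exclusion = rule
                break
        timelines.append(t)
        truths.append(truth)

    if outdir is not None:
        outdir = Path(outdir)
        write_cohort_tables(timelines, outdir)
        manifest = truth_manifest(truths)
        manifest.to_csv(outdir / "truth_manifest.csv", index=False)
        (outdir / "truth_manifest.json").write_text(
            json.dumps(manifest.to_dict(orient="records"), indent=2, default=float)
        )
    return timelines, truths


def truth_manifest(truths: list) -> pd.DataFrame:
    rows = []
    for g in truths:
        times = g.stage_times_h
        rows.append(
            {
                "patient_id": g.patient_id,
                "planted_stage": g.planted_stage,
                "mechanisms": "+".join(g.mechanisms),
                "stage1_h": times.get(1),
                "stage2_h": times.get(2),
                "stage3_h": times.get(3),
                "expected_exclusion": g.expected_exclusion or "",
                "documented_aki": g.documented_aki,
            }
        )
    return pd.DataFrame(rows)
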