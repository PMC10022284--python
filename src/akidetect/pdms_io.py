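"""Reading and writing PDMS-style delimited exports.

The on-disk cohort layout is one delimited table per signal:

``patients``    patient_id, sex, age_at_admission, surgery_type
``creatinine``  patient_id, time, value          (mg/dl; µmol/l convertible)
``urine``       patient_id, time, volume         (ml accrued since previous record)
``weight``      patient_id, time, weight         (kg)
``dialysis``    patient_id, time
``vitals``      patient_id, time
``diagnoses``   patient_id, time (may be empty), text
``drugs``       patient_id, time, drug

A :class:`TableDialect` declares the delimiter, decimal mark, timestamp
format, per-table column-name mapping, and units, so arbitrary hospital
export conventions can be adapted without touching the reader. Rows failing
type or unit validation are dropped and counted in a returned parse log;
duplicate (patient, timestamp) rows within a signal keep the *last*
occurrence, mimicking PDMS corrections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataFormatError
from .timeline import WEIGHT_BOUNDS_KG, PatientTimeline, StagePoint

#: logical columns per table (order = canonical output order)
TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "age_at_admission", "surgery_type"],
    "creatinine": ["patient_id", "time", "value"],
    "urine": ["patient_id", "time", "volume"],
    "weight": ["patient_id", "time", "weight"],
    "dialysis": ["patient_id", "time"],
    "vitals": ["patient_id", "time"],
    "diagnoses": ["patient_id", "time", "text"],
    "drugs": ["patient_id", "time", "drug"],
}

UMOL_PER_MGDL = 88.4  # creatinine: µmol/l per mg/dl


@dataclass
class TableDialect:
    """How to interpret a set of delimited export files."""

    delimiter: str = ","
    decimal: str = "."
    timestamp_format: Optional[str] = None  # None -> ISO-8601 / pandas inference
    #: per-table {logical column -> actual column name}; identity by default
    column_map: dict = field(default_factory=dict)
    #: units per signal; canonical: creatinine mg/dl, urine ml, weight kg
    units: dict = field(
        default_factory=lambda: {"creatinine": "mg/dl", "urine": "ml", "weight": "kg"}
    )

    def actual(self, table: str, logical: str) -> str:
        return self.column_map.get(table, {}).get(logical, logical)

    def validate(self) -> None:
        known_units = {
            "creatinine": {"mg/dl", "umol/l", "µmol/l"},
            "urine": {"ml", "l"},
            "weight": {"kg", "g"},
        }
        for sig, unit in self.units.items():
            if sig not in known_units:
                raise ConfigurationError(f"unknown signal {sig!r} in unit declarations")
            if unit not in known_units[sig]:
                raise ConfigurationError(f"unit {unit!r} not convertible for {sig}")
        for table, mapping in self.column_map.items():
            if table not in TABLE_COLUMNS:
                raise ConfigurationError(f"unknown table {table!r} in column map")
            targets = list(mapping.values())
            if len(targets) != len(set(targets)):
                raise ConfigurationError(f"column map for {table!r} is not one-to-one")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TableDialect":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown dialect keys: {sorted(unknown)}")
        d = cls(**mapping)
        d.validate()
        return d


@dataclass
class ParseLog:
    """Per-table row accounting; rows_in == rows_kept + rows_dropped."""

    tables: dict = field(default_factory=dict)

    def record(self, table: str, rows_in: int, rows_kept: int, duplicates: int) -> None:
        self.tables[table] = {
            "rows_in": rows_in,
            "rows_kept": rows_kept,
            "rows_dropped": rows_in - rows_kept,
            "duplicates_removed": duplicates,
        }

    def dropped(self, table: str) -> int:
        return self.tables.get(table, {}).get("rows_dropped", 0)

    def check(self) -> None:
        for t, rec in self.tables.items():
            if rec["rows_in"] != rec["rows_kept"] + rec["rows_dropped"]:
                raise DataFormatError(f"parse log for {t!r} does not conserve rows")


def _read_table(path, table: str, dialect: TableDialect) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str,
            skipinitialspace=True,
        )
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    rename = {dialect.actual(table, c): c for c in TABLE_COLUMNS[table]}
    missing = [a for a in rename if a not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing} for table {table!r}"
        )
    return df.rename(columns=rename)[TABLE_COLUMNS[table]]


def _parse_times(col: pd.Series, dialect: TableDialect) -> pd.Series:
    return pd.to_datetime(col, format=dialect.timestamp_format, errors="coerce")


def _convert_units(values: pd.Series, signal: str, dialect: TableDialect) -> pd.Series:
    unit = dialect.units.get(signal)
    if signal == "creatinine" and unit in ("umol/l", "µmol/l"):
        return values / UMOL_PER_MGDL
    if signal == "urine" and unit == "l":
        return values * 1000.0
    if signal == "weight" and unit == "g":
        return values / 1000.0
    return values


def read_cohort(
    paths: dict, dialect: Optional[TableDialect] = None
) -> tuple[list[PatientTimeline], ParseLog]:
    """Read per-table files into validated patient timelines.

    ``paths`` maps table names (see :data:`TABLE_COLUMNS`) to file paths; the
    ``patients`` table is required, every signal table is optional (an absent
    or empty table just yields empty series). Returns the timelines sorted by
    patient id and a :class:`ParseLog`.
    """
    dialect = dialect or TableDialect()
    dialect.validate()
    if "patients" not in paths:
        raise ConfigurationError("a 'patients' table is required")
    log = ParseLog()

    pat = _read_table(paths["patients"], "patients", dialect)
    n_in = len(pat)
    pat["age_at_admission"] = pd.to_numeric(pat["age_at_admission"], errors="coerce")
    ok = pat["patient_id"].notna()
    pat = pat[ok]
    dup = int(pat.duplicated("patient_id").sum())
    pat = pat.drop_duplicates("patient_id", keep="last")
    log.record("patients", n_in, len(pat), dup)
    known_ids = set(pat["patient_id"])

    value_col = {"creatinine": "value", "urine": "volume", "weight": "weight"}
    bounds = {
        "creatinine": (0.0, np.inf, False),  # strictly positive
        "urine": (0.0, np.inf, True),  # zero allowed
        "weight": WEIGHT_BOUNDS_KG + (False,),
    }
    parsed: dict[str, pd.DataFrame] = {}
    for table in ("creatinine", "urine", "weight", "dialysis", "vitals", "drugs", "diagnoses"):
        if table not in paths:
            continue
        df = _read_table(paths[table], table, dialect)
        n_in = len(df)
        df["time"] = _parse_times(df["time"], dialect)
        keep = df["patient_id"].isin(known_ids)
        if table == "diagnoses":
            keep &= df["text"].notna()  # undated diagnoses are allowed
        else:
            keep &= df["time"].notna()
        if table in value_col:
            col = value_col[table]
            if dialect.decimal != ".":
                df[col] = df[col].str.replace(dialect.decimal, ".", regex=False)
            df[col] = pd.to_numeric(df[col], errors="coerce")
            df[col] = _convert_units(df[col], table, dialect)
            lo, hi, inclusive = bounds[table]
            in_range = (df[col] >= lo) if inclusive else (df[col] > lo)
            keep &= df[col].notna() & in_range & (df[col] < hi)
        if table == "drugs":
            keep &= df["drug"].notna()
        df = df[keep]
        dup = int(df.duplicated(["patient_id", "time"]).sum())
        if table not in ("diagnoses", "drugs"):  # events/series dedupe; lists keep all
            df = df.drop_duplicates(["patient_id", "time"], keep="last")
        else:
            dup = 0
        df = df.sort_values(["patient_id", "time"])
        log.record(table, n_in, len(df) + (0 if table in ("diagnoses", "drugs") else 0), dup)
        # rows_kept excludes dedupe removals: recount
        log.tables[table]["rows_kept"] = len(df)
        log.tables[table]["rows_dropped"] = n_in - len(df)
        parsed[table] = df

    timelines = []
    for _, prow in pat.sort_values("patient_id").iterrows():
        pid = prow["patient_id"]

        def rows(table):
            df = parsed.get(table)
            if df is None:
                return None
            return df[df["patient_id"] == pid]

        def series(table):
            df = rows(table)
            if df is None or len(df) == 0:
                return []
            return list(zip(df["time"], df[value_col[table]]))

        def times(table):
            df = rows(table)
            return [] if df is None else list(df["time"])

        sex = prow["sex"] if prow["sex"] in ("male", "female") else "unknown"
        age = prow["age_at_admission"]
        diag = rows("diagnoses")
        drug = rows("drugs")
        timelines.append(
            PatientTimeline(
                patient_id=pid,
                sex=sex,
                age_at_admission=int(age) if pd.notna(age) else None,
                surgery_type=prow["surgery_type"] if pd.notna(prow["surgery_type"]) else "unknown",
                weight_series=series("weight"),
                creatinine_series=series("creatinine"),
                urine_series=series("urine"),
                dialysis_events=times("dialysis"),
                vital_timestamps=times("vitals"),
                diagnosis_texts=(
                    []
                    if diag is None
                    else [
                        (t if pd.notna(t) else None, x)
                        for t, x in zip(diag["time"], diag["text"])
                    ]
                ),
                drug_admins=(
                    [] if drug is None else list(zip(drug["time"], drug["drug"]))
                ),
            )
        )
    log.check()
    return timelines, log


# ---------------------------------------------------------------------------
# cohort tables out (used by the simulator and for round-trips)
# ---------------------------------------------------------------------------

def write_cohort_tables(timelines, outdir) -> dict:
    """Write timelines as the canonical per-signal tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {t: [] for t in TABLE_COLUMNS}
    for t in timelines:
        frames["patients"].append(
            (t.patient_id, t.sex, t.age_at_admission, t.surgery_type)
        )
        frames["creatinine"] += [(t.patient_id, ts, v) for ts, v in t.creatinine_series.items()]
        frames["urine"] += [(t.patient_id, ts, v) for ts, v in t.urine_series.items()]
        frames["weight"] += [(t.patient_id, ts, v) for ts, v in t.weight_series.items()]
        frames["dialysis"] += [(t.patient_id, ts) for ts in t.dialysis_events]
        frames["vitals"] += [(t.patient_id, ts) for ts in t.vital_timestamps]
        frames["diagnoses"] += [(t.patient_id, ts, x) for ts, x in t.diagnosis_texts]
        frames["drugs"] += [(t.patient_id, ts, d) for ts, d in t.drug_admins]
    paths = {}
    for table, cols in TABLE_COLUMNS.items():
        path = outdir / f"{table}.csv"
        pd.DataFrame(frames[table], columns=cols).to_csv(path, index=False)
        paths[table] = path
    return paths


# ---------------------------------------------------------------------------
# stage series
# ---------------------------------------------------------------------------

STAGE_SERIES_COLUMNS = ["patient_id", "time", "stage", "criterion", "evidence"]


def write_stage_series(detections: dict, path) -> None:
    """Write per-patient StagePoint series as one delimited row per point.

    ``detections`` maps patient_id -> ordered list of :class:`StagePoint`.
    """
    rows = []
    for pid, points in detections.items():
        for p in points:
            rows.append(
                {
                    "patient_id": pid,
                    "time": p.time.isoformat(),
                    "stage": p.stage,
                    "criterion": p.criterion,
                    "evidence": json.dumps(p.evidence, default=float, sort_keys=True),
                }
            )
    pd.DataFrame(rows, columns=STAGE_SERIES_COLUMNS).to_csv(path, index=False)


def read_stage_series(path) -> dict:
    """Inverse of :func:`write_stage_series`."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # noqa: BLE001
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    out: dict[str, list[StagePoint]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["patient_id"], []).append(
            StagePoint(
                time=pd.Timestamp(row["time"]),
                stage=int(row["stage"]),
                criterion=row["criterion"],
                evidence=json.loads(row["evidence"]) if pd.notna(row["evidence"]) else {},
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort frame (per-patient detection summary table)
# ---------------------------------------------------------------------------

def write_cohort_frame(frame: pd.DataFrame, path) -> None:
    df = frame.reset_index().copy()
    df["criteria_at_max"] = df["criteria_at_max"].apply(
        lambda s: "+".join(sorted(s)) if s else ""
    )
    df.to_csv(path, index=False)


def read_cohort_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["criteria_at_max"] = df["criteria_at_max"].apply(
        lambda s: frozenset(s.split("+")) if isinstance(s, str) and s else frozenset()
    )
    return df.set_index("patient_id")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(report, outdir, format: str = "delimited") -> list:
    """Serialise a :class:`~akidetect.analytics.CohortReport`.

    ``delimited`` writes one CSV per table; ``json`` writes a single document
    keyed by table name. Percentage columns are already rounded to one
    decimal by the analytics layer. Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = report.tables()
    if format == "delimited":
        for name, df in tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        meta = {"n_patients": report.n_patients}
        if report.underrepresentation is not None:
            meta["underrepresentation"] = report.underrepresentation
        path = outdir / "report_meta.json"
        path.write_text(json.dumps(meta, indent=2, default=float))
        written.append(path)
    elif format == "json":
        doc = {"n_patients": report.n_patients}
        for name, df in tables.items():
            doc[name] = df.to_dict(orient="records")
        if report.underrepresentation is not None:
            doc["underrepresentation"] = report.underrepresentation
        path = outdir / "report.json"
        path.write_text(json.dumps(doc, indent=2, default=_json_default))
        written.append(path)
    else:
        raise ConfigurationError(f"unknown report format {format!r}")
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if obj is pd.NaT or (isinstance(obj, float) and np.isnan(obj)):
        return None
    return str(obj)


def load_config(path) -> dict:
    """Load a YAML config file with optional kdigo/dialect/exclusions/simulate sections."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return doc
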