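"""Reading, validation and normalisation of CGM traces and cohort metadata.

All glucose values are held internally in mmol/L at 2-decimal precision;
timestamps are naive local clock times at minute resolution (hour-of-day
binning works on the wall clock, so no timezone arithmetic is performed).
Two CSV dialects are understood: a canonical *normalized* dialect written by
this package, and a Dexcom-CLARITY-style export.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Conversion factor between mg/dL and mmol/L for glucose.
MGDL_PER_MMOL = 18.016

#: Default device reporting floor: readings below are exported as "Low".
DEFAULT_FLOOR = 2.2
#: Default device reporting ceiling: readings above are exported as "High".
DEFAULT_CEILING = 22.2

ClipFlag = Literal["", "low", "high"]

NORMALIZED_HEADER = ["patient_id", "timestamp", "glucose_mmol_l", "clipped"]
METADATA_HEADER = [
    "patient_id", "diagnosis", "sex", "age_months", "mutation",
    "hi_type", "surgery", "medication", "location",
]
EXCLUSIONS_HEADER = ["patient_id", "start", "end", "reason"]

_TS_FORMAT = "%Y-%m-%dT%H:%M"


def mgdl_to_mmol(value: float) -> float:
    """Convert mg/dL to mmol/L, rounded to 2 decimals."""
    return round(value / MGDL_PER_MMOL, 2)


def mmol_to_mgdl(value: float) -> float:
    """Convert mmol/L to mg/dL, rounded to 2 decimals."""
    return round(value * MGDL_PER_MMOL, 2)


@dataclass(frozen=True)
class GlucoseReading:
    """One sensor glucose value at a local clock time.

    ``clipped`` marks values censored at the device reporting limits: a
    ``"low"`` reading carries the device floor (true glucose is at or below
    it), a ``"high"`` reading the ceiling.
    """

    timestamp: datetime
    value: float
    clipped: ClipFlag = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"glucose must be positive, got {self.value}")
        if self.clipped not in ("", "low", "high"):
            raise ValueError(f"bad clip flag {self.clipped!r}")


@dataclass
class GlucoseTrace:
    """One patient's ordered CGM readings at a nominal epoch length.

    Monitored time is accounted as ``nominal_epoch`` minutes per reading:
    gaps between readings contribute nothing, so a trace with dropout simply
    has fewer monitored minutes.
    """

    patient_id: str
    readings: list[GlucoseReading]
    device: str = "other"
    nominal_epoch: int = 5

    def __post_init__(self) -> None:
        for prev, cur in zip(self.readings, self.readings[1:]):
            if cur.timestamp <= prev.timestamp:
                raise ValueError(
                    f"{self.patient_id}: readings not strictly increasing at "
                    f"{cur.timestamp}"
                )

    @property
    def n_readings(self) -> int:
        return len(self.readings)

    @property
    def monitored_minutes(self) -> int:
        return self.nominal_epoch * len(self.readings)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.readings], dtype=float)


@dataclass(frozen=True)
class PatientRecord:
    """Cohort metadata for one patient (demographics + clinical labels)."""

    patient_id: str
    diagnosis: Literal["HI", "IKH"]
    sex: Literal["male", "female"]
    age_months: int
    mutation: str = "not-done"          # "positive:<gene>" | "negative" | "not-done"
    hi_type: str = "n/a"                # diffuse | focal | n/a
    surgery: str = "n/a"                # none | lesionectomy | subtotal | n/a
    medication: tuple[str, ...] = ()
    location: str = "outpatient"        # inpatient | outpatient

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError("age_months must be >= 0")
        if self.diagnosis == "IKH" and (self.hi_type, self.surgery) != ("n/a", "n/a"):
            raise ValueError("IKH patients must have hi_type and surgery = n/a")

    @property
    def mutation_positive(self) -> bool:
        return self.mutation.startswith("positive")

    @property
    def on_medication(self) -> bool:
        return len(self.medication) > 0


@dataclass(frozen=True)
class ExclusionInterval:
    """Half-open interval [start, end) of data to delete from a trace,
    e.g. an in-hospital controlled fast."""

    patient_id: str
    start: datetime
    end: datetime
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("exclusion interval requires start < end")


def _parse_timestamp(text: str, row: int) -> datetime:
    text = text.strip()
    for fmt in (_TS_FORMAT, "%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M"):
        try:
            ts = datetime.strptime(text, fmt)
            return ts.replace(second=0, microsecond=0)
        except ValueError:
            continue
    raise ValueError(f"row {row}: unparseable timestamp {text!r}")


def _finish_trace(
    patient_id: str,
    rows: list[tuple[datetime, float, str]],
    device: str,
    nominal_epoch: int,
) -> GlucoseTrace:
    rows.sort(key=lambda r: r[0])  # stable: keeps file order among duplicates
    readings: list[GlucoseReading] = []
    n_dup = 0
    for ts, value, flag in rows:
        if readings and readings[-1].timestamp == ts:
            n_dup += 1
            continue
        readings.append(GlucoseReading(ts, value, flag))
    if n_dup:
        logger.warning("%s: dropped %d duplicate-timestamp readings", patient_id, n_dup)
    return GlucoseTrace(patient_id, readings, device=device, nominal_epoch=nominal_epoch)


def parse_cgm_csv(
    path: str | Path,
    dialect: Literal["clarity", "normalized"] = "normalized",
    units: Literal["mmol_L", "mg_dL", "auto"] = "auto",
    patient_id: str | None = None,
    device: str = "other",
    floor: float = DEFAULT_FLOOR,
    ceiling: float = DEFAULT_CEILING,
    nominal_epoch: int = 5,
) -> GlucoseTrace:
    """Read one patient's CGM trace from a CSV file.

    Parameters
    ----------
    path
        CSV file. For ``dialect="normalized"`` the header is
        ``patient_id,timestamp,glucose_mmol_l,clipped``; for
        ``dialect="clarity"`` the Dexcom CLARITY export columns
        (``Timestamp (...)``, ``Event Type``, ``Glucose Value (mg/dL)`` or
        ``(mmol/L)``) are expected and only EGV rows are kept.
    units
        ``auto`` infers units from the dialect/column name; an explicit unit
        overrides it for generically named columns.
    patient_id
        Required for the CLARITY dialect (the export carries no id column);
        overrides the file's id for the normalized dialect when given.

    Textual ``Low``/``High`` values are imputed at ``floor``/``ceiling`` and
    flagged as clipped. Readings are sorted and de-duplicated (first wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "normalized":
        return _parse_normalized(path, patient_id, device, floor, ceiling, nominal_epoch)
    if dialect == "clarity":
        if patient_id is None:
            raise ValueError("patient_id is required for the clarity dialect")
        return _parse_clarity(path, patient_id, units, device, floor, ceiling, nominal_epoch)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_normalized(
    path: Path,
    patient_id: str | None,
    device: str,
    floor: float,
    ceiling: float,
    nominal_epoch: int,
) -> GlucoseTrace:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = set(NORMALIZED_HEADER) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        rows: list[tuple[datetime, float, str]] = []
        pid = patient_id
        for i, rec in enumerate(reader, start=2):
            pid = pid or rec["patient_id"]
            ts = _parse_timestamp(rec["timestamp"], i)
            raw = rec["glucose_mmol_l"].strip()
            flag = (rec.get("clipped") or "").strip().lower()
            if raw.lower() == "low":
                value, flag = floor, "low"
            elif raw.lower() == "high":
                value, flag = ceiling, "high"
            else:
                value = round(float(raw), 2)
            if flag not in ("", "low", "high"):
                raise ValueError(f"{path} row {i}: bad clipped flag {flag!r}")
            rows.append((ts, value, flag))
    if not rows:
        raise ValueError(f"{path}: no readings")
    return _finish_trace(pid or path.stem, rows, device, nominal_epoch)


def _parse_clarity(
    path: Path,
    patient_id: str,
    units: str,
    device: str,
    floor: float,
    ceiling: float,
    nominal_epoch: int,
) -> GlucoseTrace:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        ts_col = _find_column(reader.fieldnames, "Timestamp", path)
        type_col = _find_column(reader.fieldnames, "Event Type", path)
        glu_col = _find_column(reader.fieldnames, "Glucose Value", path)
        if units == "auto":
            if "mg/dl" in glu_col.lower():
                units = "mg_dL"
            elif "mmol/l" in glu_col.lower():
                units = "mmol_L"
            else:
                raise ValueError(
                    f"{path}: cannot infer units from column {glu_col!r}; "
                    "pass units explicitly"
                )
        rows: list[tuple[datetime, float, str]] = []
        for i, rec in enumerate(reader, start=2):
            if (rec.get(type_col) or "").strip() != "EGV":
                continue  # calibration, alert and device rows are not glucose
            ts = _parse_timestamp(rec[ts_col], i)
            raw = (rec.get(glu_col) or "").strip()
            if raw.lower() == "low":
                rows.append((ts, floor, "low"))
                continue
            if raw.lower() == "high":
                rows.append((ts, ceiling, "high"))
                continue
            value = float(raw)
            if units == "mg_dL":
                value = mgdl_to_mmol(value)
            else:
                value = round(value, 2)
            rows.append((ts, value, ""))
    if not rows:
        raise ValueError(f"{path}: no EGV readings")
    return _finish_trace(patient_id, rows, device, nominal_epoch)


def _find_column(fieldnames: Sequence[str], prefix: str, path: Path) -> str:
    for name in fieldnames:
        if name.startswith(prefix):
            return name
    raise ValueError(f"{path}: no column starting with {prefix!r}")


def write_trace_csv(trace: GlucoseTrace, path: str | Path) -> None:
    """Write a trace in the normalized dialect (round-trips exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NORMALIZED_HEADER)
        for r in trace.readings:
            writer.writerow(
                [trace.patient_id, r.timestamp.strftime(_TS_FORMAT),
                 f"{r.value:.2f}", r.clipped]
            )


def exclude_intervals(
    trace: GlucoseTrace, exclusions: Iterable[ExclusionInterval]
) -> GlucoseTrace:
    """Drop readings falling in any half-open exclusion interval [start, end).

    Exclusions for other patients are ignored. The empty list is the
    identity; monitored minutes never increase.
    """
    spans = [
        (e.start, e.end) for e in exclusions if e.patient_id == trace.patient_id
    ]
    if not spans:
        return trace
    kept = [
        r for r in trace.readings
        if not any(s <= r.timestamp < e for s, e in spans)
    ]
    return replace(trace, readings=kept)


def read_metadata_csv(path: str | Path) -> list[PatientRecord]:
    """Read the cohort metadata table. ``medication`` is a ``;``-separated
    list (empty = off medication)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(METADATA_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        meds = tuple(m for m in row["medication"].split(";") if m)
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                diagnosis=row["diagnosis"],
                sex=row["sex"],
                age_months=int(row["age_months"]),
                mutation=row["mutation"] or "not-done",
                hi_type=row["hi_type"] or "n/a",
                surgery=row["surgery"] or "n/a",
                medication=meds,
                location=row["location"] or "outpatient",
            )
        )
    return records


def write_metadata_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_HEADER)
        for r in records:
            writer.writerow(
                [r.patient_id, r.diagnosis, r.sex, r.age_months, r.mutation,
                 r.hi_type, r.surgery, ";".join(r.medication), r.location]
            )


def read_exclusions_csv(path: str | Path) -> list[ExclusionInterval]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(EXCLUSIONS_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExclusionInterval(
            patient_id=row["patient_id"],
            start=_parse_timestamp(row["start"], i + 2),
            end=_parse_timestamp(row["end"], i + 2),
            reason=row["reason"],
        )
        for i, row in df.iterrows()
    ]


def _mean_sd(values: Sequence[float], label: str) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    if arr.size == 1:
        logger.warning("%s: single observation, SD reported as 0", label)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def cohort_summary(
    records: Sequence[PatientRecord],
    months_since_diagnosis: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-diagnosis demographic table: counts by sex, mean (SD) age, and
    mean (SD) months since diagnosis where supplied.

    Patients with missing ages cannot occur (the record requires an age);
    missing time-since-diagnosis entries are excluded from that mean with a
    logged count.
    """
    if not records:
        raise ValueError("cohort_summary requires at least one record")
    rows = {}
    for diag in sorted({r.diagnosis for r in records}):
        group = [r for r in records if r.diagnosis == diag]
        age_mean, age_sd = _mean_sd([r.age_months for r in group], f"{diag} age")
        row = {
            "n": len(group),
            "n_male": sum(r.sex == "male" for r in group),
            "n_female": sum(r.sex == "female" for r in group),
            "age_months_mean": age_mean,
            "age_months_sd": age_sd,
        }
        if months_since_diagnosis is not None:
            present = [
                months_since_diagnosis[r.patient_id]
                for r in group
                if r.patient_id in months_since_diagnosis
            ]
            n_missing = len(group) - len(present)
            if n_missing:
                logger.warning(
                    "%s: %d patients missing time-since-diagnosis", diag, n_missing
                )
            tsd_mean, tsd_sd = _mean_sd(present, f"{diag} time-since-diagnosis")
            row["months_since_diagnosis_mean"] = tsd_mean
            row["months_since_diagnosis_sd"] = tsd_sd
        rows[diag] = row
    return pd.DataFrame.from_dict(rows, orient="index")
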