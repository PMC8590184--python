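"""Hypoglycemia episode segmentation and episode/cohort statistics.

A hypoglycemia event is a maximal run of consecutive CGM readings strictly
below the analysis threshold (default 3.5 mmol/L). Each reading stands for
one nominal epoch (default 5 minutes), so the minimum event duration is one
epoch and an event's duration is ``n_epochs * epoch_minutes`` — never
``end - start``, which would silently bridge sensor gaps. A gap between
consecutive readings longer than ``max_gap_minutes`` (default 1.5 epochs)
breaks a run: unobserved time is never counted as hypoglycemia.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GlucoseTrace

__all__ = [
    "DetectionConfig",
    "HypoEvent",
    "CohortEventStats",
    "detect_events",
    "filter_prolonged",
    "cohort_event_stats",
    "write_events_csv",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of episode detection.

    threshold
        Hypoglycemia cutoff in mmol/L; readings strictly below it count.
    epoch_minutes
        Nominal sensor reporting interval; the unit of minute accounting.
    max_gap_minutes
        Largest inter-reading gap over which a run may continue.
    prolonged_minutes
        Cutoff for "prolonged" events (strictly greater than).
    """

    threshold: float = 3.5
    epoch_minutes: float = 5.0
    max_gap_minutes: float = 7.5
    prolonged_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_minutes <= 0:
            raise ValueError("epoch_minutes must be positive")
        if self.max_gap_minutes < self.epoch_minutes:
            raise ValueError("max_gap_minutes must be >= epoch_minutes")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class HypoEvent:
    """One maximal below-threshold run.

    ``start``/``end`` are the timestamps of the first and last
    below-threshold readings; ``duration_minutes = n_epochs * epoch``.
    ``nadir_clipped`` marks events whose minimum sits at the device floor,
    i.e. the true nadir is unknown.
    """

    patient_id: str
    start: datetime
    end: datetime
    n_epochs: int
    duration_minutes: float
    nadir: float
    nadir_clipped: bool = False


def detect_events(trace: GlucoseTrace, config: DetectionConfig | None = None) -> list[HypoEvent]:
    """Segment a trace into maximal hypoglycemia events.

    Consecutiveness requires both below-threshold values and an
    inter-reading gap of at most ``config.max_gap_minutes``. Every
    below-threshold reading belongs to exactly one event.
    """
    config = config or DetectionConfig(epoch_minutes=trace.nominal_epoch)
    events: list[HypoEvent] = []
    run: list = []

    def flush() -> None:
        if not run:
            return
        nadir_reading = min(run, key=lambda r: r.value)
        events.append(
            HypoEvent(
                patient_id=trace.patient_id,
                start=run[0].timestamp,
                end=run[-1].timestamp,
                n_epochs=len(run),
                duration_minutes=len(run) * config.epoch_minutes,
                nadir=nadir_reading.value,
                nadir_clipped=any(
                    r.clipped == "low" for r in run if r.value == nadir_reading.value
                ),
            )
        )
        run.clear()

    for reading in trace.readings:
        if reading.value < config.threshold:
            if run:
                gap = (reading.timestamp - run[-1].timestamp).total_seconds() / 60.0
                if gap > config.max_gap_minutes:
                    flush()
            run.append(reading)
        else:
            flush()
    flush()
    return events


def filter_prolonged(
    events: Iterable[HypoEvent], config: DetectionConfig | None = None
) -> list[HypoEvent]:
    """Events lasting strictly more than ``prolonged_minutes`` (order kept)."""
    config = config or DetectionConfig()
    return [e for e in events if e.duration_minutes > config.prolonged_minutes]


@dataclass
class CohortEventStats:
    """Cohort-level event statistics (durations/nadirs use sample SD)."""

    n_events: int
    total_hypo_minutes: float
    total_monitored_minutes: float
    percent_time_hypo: float
    mean_duration: float
    sd_duration: float
    mean_nadir: float
    sd_nadir: float
    per_patient_counts: dict[str, int]
    n_prolonged: int
    mean_prolonged_duration: float
    mean_prolonged_nadir: float

    @property
    def mean_events_per_patient(self) -> float:
        if not self.per_patient_counts:
            return float("nan")
        return float(np.mean(list(self.per_patient_counts.values())))

    @property
    def sd_events_per_patient(self) -> float:
        counts = list(self.per_patient_counts.values())
        if len(counts) < 2:
            return 0.0
        return float(np.std(counts, ddof=1))


def _sample_sd(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1))


def cohort_event_stats(
    events_by_patient: Mapping[str, Sequence[HypoEvent]],
    traces: Sequence[GlucoseTrace],
    config: DetectionConfig | None = None,
) -> CohortEventStats:
    """Aggregate per-patient event lists into cohort statistics.

    Patients with a trace but no events appear in ``per_patient_counts``
    with 0. Raises if the cohort has zero monitored minutes (percent time
    hypoglycemic would be undefined).
    """
    config = config or DetectionConfig()
    trace_ids = {t.patient_id for t in traces}
    unknown = set(events_by_patient) - trace_ids
    if unknown:
        raise ValueError(f"events for patients without traces: {sorted(unknown)}")
    total_monitored = float(sum(t.monitored_minutes for t in traces))
    if total_monitored == 0:
        raise ValueError("zero monitored minutes: percent time hypoglycemic undefined")

    all_events = [e for evs in events_by_patient.values() for e in evs]
    durations = np.array([e.duration_minutes for e in all_events], dtype=float)
    nadirs = np.array([e.nadir for e in all_events], dtype=float)
    total_hypo = float(durations.sum())

    counts = {t.patient_id: 0 for t in traces}
    for pid, evs in events_by_patient.items():
        counts[pid] = len(evs)

    prolonged = filter_prolonged(all_events, config)
    p_durations = np.array([e.duration_minutes for e in prolonged], dtype=float)
    p_nadirs = np.array([e.nadir for e in prolonged], dtype=float)

    return CohortEventStats(
        n_events=len(all_events),
        total_hypo_minutes=total_hypo,
        total_monitored_minutes=total_monitored,
        percent_time_hypo=100.0 * total_hypo / total_monitored,
        mean_duration=float(durations.mean()) if durations.size else math.nan,
        sd_duration=_sample_sd(durations),
        mean_nadir=float(nadirs.mean()) if nadirs.size else math.nan,
        sd_nadir=_sample_sd(nadirs),
        per_patient_counts=counts,
        n_prolonged=len(prolonged),
        mean_prolonged_duration=float(p_durations.mean()) if p_durations.size else math.nan,
        mean_prolonged_nadir=float(p_nadirs.mean()) if p_nadirs.size else math.nan,
    )


def write_events_csv(events: Iterable[HypoEvent], path: str | Path) -> None:
    """Write events as ``patient_id,start,end,n_epochs,duration_min,nadir_mmol_l,nadir_clipped``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "start", "end", "n_epochs", "duration_min",
             "nadir_mmol_l", "nadir_clipped"]
        )
        for e in events:
            writer.writerow(
                [e.patient_id, e.start.strftime("%Y-%m-%dT%H:%M"),
                 e.end.strftime("%Y-%m-%dT%H:%M"), e.n_epochs,
                 f"{e.duration_minutes:g}", f"{e.nadir:.2f}",
                 "true" if e.nadir_clipped else "false"]
            )
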