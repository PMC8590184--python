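"""Hour-of-day binning of monitored and hypoglycemic time, clock-window
summaries, and hypoglycemia-threshold sweeps.

Minute accounting follows the 5-minute epoch convention: each reading
credits one whole epoch to the hour bin of its own timestamp (an epoch
starting 03:55 belongs wholly to hour 3). Clock windows are half-open
``[start:00, end:00)`` and may wrap midnight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import DetectionConfig, HypoEvent, detect_events
from .io import GlucoseTrace

__all__ = [
    "ClockWindow",
    "EARLY_HOURS",
    "HourlyProfile",
    "WindowSummary",
    "ThresholdSweepResult",
    "minutes_by_hour",
    "window_summary",
    "summary_from_counts",
    "threshold_sweep",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention), e.g. 2.5 -> 3."""
    value = float(value)
    if math.isnan(value):
        return value
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClockWindow:
    """Half-open daily clock window [start_hour:00, end_hour:00).

    ``start_hour > end_hour`` wraps midnight, e.g. ``ClockWindow(18, 1)``
    is 6 PM–1 AM (width 7 h).
    """

    start_hour: int
    end_hour: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_hour <= 23 and 0 <= self.end_hour <= 24):
            raise ValueError("hours must satisfy 0<=start<=23, 0<=end<=24")
        if self.start_hour == self.end_hour % 24:
            raise ValueError("zero-width window")

    @property
    def hours(self) -> tuple[int, ...]:
        if self.start_hour < self.end_hour:
            return tuple(range(self.start_hour, self.end_hour))
        return tuple(range(self.start_hour, 24)) + tuple(range(0, self.end_hour))

    @property
    def width_hours(self) -> int:
        return len(self.hours)

    def contains(self, hour: int) -> bool:
        return hour in self.hours

    @classmethod
    def from_string(cls, text: str, label: str = "") -> "ClockWindow":
        """Parse ``"HH:MM-HH:MM"`` (minutes must be :00) or ``"H-H"``."""
        try:
            start, end = text.split("-")
            sh, sm = (start.split(":") + ["0"])[:2]
            eh, em = (end.split(":") + ["0"])[:2]
            if int(sm) != 0 or int(em) != 0:
                raise ValueError
            end_h = int(eh)
            return cls(int(sh), 24 if end_h == 0 else end_h, label=label or text)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bad window {text!r}; expected HH:00-HH:00") from exc

    def __str__(self) -> str:
        return f"{self.start_hour:02d}:00-{self.end_hour % 24:02d}:00"


#: The high-risk period reported for hyperinsulinism: 3 AM to 7 AM.
EARLY_HOURS = ClockWindow(3, 7, label="early hours")


@dataclass
class HourlyProfile:
    """Monitored / hypoglycemic minutes and event starts per clock hour."""

    monitored_minutes: np.ndarray  # shape (24,)
    hypo_minutes: np.ndarray       # shape (24,)
    event_starts: np.ndarray       # shape (24,), integer counts

    def __post_init__(self) -> None:
        for name in ("monitored_minutes", "hypo_minutes", "event_starts"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (24,):
                raise ValueError(f"{name} must have shape (24,)")
            setattr(self, name, arr)
        if np.any(self.hypo_minutes > self.monitored_minutes):
            raise ValueError("hypo minutes exceed monitored minutes in a bin")

    @property
    def percent(self) -> np.ndarray:
        """Percent time hypoglycemic per hour (NaN where unmonitored)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.monitored_minutes > 0,
                100.0 * self.hypo_minutes / self.monitored_minutes,
                np.nan,
            )

    @property
    def total_monitored(self) -> float:
        return float(self.monitored_minutes.sum())

    @property
    def total_hypo(self) -> float:
        return float(self.hypo_minutes.sum())

    @property
    def total_events(self) -> int:
        return int(self.event_starts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hour": np.arange(24),
                "monitored_min": self.monitored_minutes,
                "hypo_min": self.hypo_minutes,
                "percent": self.percent,
                "event_starts": self.event_starts.astype(int),
            }
        )


def minutes_by_hour(
    traces: Sequence[GlucoseTrace] | GlucoseTrace,
    events_by_patient: Mapping[str, Sequence[HypoEvent]],
    config: DetectionConfig | None = None,
) -> HourlyProfile:
    """Pool traces into a 24-bin hour-of-day profile.

    Each reading adds one epoch of monitored time to its hour, and of
    hypoglycemic time iff strictly below the threshold; event start hours
    come from the first below-threshold reading of each event.
    """
    if isinstance(traces, GlucoseTrace):
        traces = [traces]
    config = config or DetectionConfig()
    monitored = np.zeros(24)
    hypo = np.zeros(24)
    starts = np.zeros(24)
    for trace in traces:
        epoch = config.epoch_minutes
        for r in trace.readings:
            h = r.timestamp.hour
            monitored[h] += epoch
            if r.value < config.threshold:
                hypo[h] += epoch
    for evs in events_by_patient.values():
        for e in evs:
            starts[e.start.hour] += 1
    return HourlyProfile(monitored, hypo, starts)


@dataclass(frozen=True)
class WindowSummary:
    """Inside/outside minute accounting for one clock window.

    ``hypo_share_inside`` is the percentage of all hypoglycemic minutes that
    fall inside the window; under a uniform distribution of hypoglycemia it
    would equal ``expected_share`` (window width / 24 h).
    """

    window: ClockWindow
    inside_monitored: float
    inside_hypo: float
    outside_monitored: float
    outside_hypo: float

    @property
    def inside_percent(self) -> float:
        return 100.0 * self.inside_hypo / self.inside_monitored

    @property
    def outside_percent(self) -> float:
        if self.outside_monitored == 0:
            return math.nan
        return 100.0 * self.outside_hypo / self.outside_monitored

    @property
    def total_hypo(self) -> float:
        return self.inside_hypo + self.outside_hypo

    @property
    def hypo_share_inside(self) -> float:
        if self.total_hypo == 0:
            return math.nan
        return 100.0 * self.inside_hypo / self.total_hypo

    @property
    def expected_share(self) -> float:
        return 100.0 * self.window.width_hours / 24.0

    @property
    def risk_ratio(self) -> float:
        """Inside percent / outside percent; NaN when undefined (flagged)."""
        out = self.outside_percent
        if not out or math.isnan(out):
            return math.nan
        return self.inside_percent / out

    def to_dict(self) -> dict:
        return {
            "window": str(self.window),
            "label": self.window.label,
            "inside_monitored": self.inside_monitored,
            "inside_hypo": self.inside_hypo,
            "outside_monitored": self.outside_monitored,
            "outside_hypo": self.outside_hypo,
            "inside_percent": self.inside_percent,
            "outside_percent": self.outside_percent,
            "hypo_share_inside": self.hypo_share_inside,
            "expected_share": self.expected_share,
            "risk_ratio": self.risk_ratio,
        }


def window_summary(profile: HourlyProfile, window: ClockWindow) -> WindowSummary:
    """Summarise a clock window against the rest of the day."""
    mask = np.zeros(24, dtype=bool)
    mask[list(window.hours)] = True
    inside_mon = float(profile.monitored_minutes[mask].sum())
    if inside_mon == 0:
        raise ValueError(f"window {window} has zero monitored minutes")
    return WindowSummary(
        window=window,
        inside_monitored=inside_mon,
        inside_hypo=float(profile.hypo_minutes[mask].sum()),
        outside_monitored=float(profile.monitored_minutes[~mask].sum()),
        outside_hypo=float(profile.hypo_minutes[~mask].sum()),
    )


def summary_from_counts(
    window: ClockWindow,
    inside_hypo: float,
    inside_monitored: float,
    outside_hypo: float,
    outside_monitored: float,
) -> WindowSummary:
    """Build a WindowSummary directly from minute counts (e.g. published
    contingency totals), bypassing trace-level binning."""
    if inside_monitored <= 0:
        raise ValueError("inside_monitored must be positive")
    return WindowSummary(
        window, inside_monitored, inside_hypo, outside_monitored, outside_hypo
    )


@dataclass
class ThresholdSweepResult:
    """Detection + window summary re-run at each hypoglycemia threshold."""

    window: ClockWindow
    thresholds: list[float]
    n_events: dict[float, int]
    total_hypo_minutes: dict[float, float]
    summaries: dict[float, WindowSummary]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for th in self.thresholds:
            s = self.summaries[th]
            rows.append(
                {
                    "threshold": th,
                    "n_events": self.n_events[th],
                    "total_hypo_min": self.total_hypo_minutes[th],
                    "inside_percent": s.inside_percent,
                    "outside_percent": s.outside_percent,
                    "hypo_share_inside": s.hypo_share_inside,
                }
            )
        return pd.DataFrame(rows)


def threshold_sweep(
    traces: Sequence[GlucoseTrace],
    thresholds: Iterable[float],
    window: ClockWindow,
    config: DetectionConfig | None = None,
    floor: float = 2.2,
) -> ThresholdSweepResult:
    """Re-run detection and window summarisation at each threshold.

    Thresholds at or below the device floor are refused: every clipped
    "Low" reading would be ambiguous there. Total hypoglycemic minutes are
    checked to be nonincreasing as the threshold decreases.
    """
    base = config or DetectionConfig()
    thresholds = sorted(set(float(t) for t in thresholds), reverse=True)
    for th in thresholds:
        if th <= floor:
            raise ValueError(
                f"threshold {th} is at or below the device floor {floor}"
            )
    n_events: dict[float, int] = {}
    hypo_min: dict[float, float] = {}
    summaries: dict[float, WindowSummary] = {}
    for th in thresholds:
        cfg = DetectionConfig(
            threshold=th,
            epoch_minutes=base.epoch_minutes,
            max_gap_minutes=base.max_gap_minutes,
            prolonged_minutes=base.prolonged_minutes,
        )
        events = {t.patient_id: detect_events(t, cfg) for t in traces}
        profile = minutes_by_hour(traces, events, cfg)
        n_events[th] = sum(len(v) for v in events.values())
        hypo_min[th] = profile.total_hypo
        summaries[th] = window_summary(profile, window)
    for hi, lo in zip(thresholds, thresholds[1:]):
        assert hypo_min[lo] <= hypo_min[hi], "hypo minutes must shrink with threshold"
    return ThresholdSweepResult(window, thresholds, n_events, hypo_min, summaries)
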