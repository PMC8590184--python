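"""Model/results interface tying the pipeline together.

:class:`HypoglycemiaTemporalModel` is constructed from CGM traces (plus
optional cohort metadata), and :meth:`fit` runs episode detection,
hour-of-day profiling, window summaries with chi-square tests, subgroup
comparisons and an optional threshold sweep, returning a
:class:`TemporalRiskResults` with a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as cio
from .events import (
    CohortEventStats,
    DetectionConfig,
    HypoEvent,
    cohort_event_stats,
    detect_events,
    filter_prolonged,
)
from .profiles import (
    ClockWindow,
    EARLY_HOURS,
    HourlyProfile,
    ThresholdSweepResult,
    WindowSummary,
    minutes_by_hour,
    round_half_up,
    threshold_sweep,
    window_summary,
)
from .stats import (
    SubgroupComparison,
    TestResult,
    build_minutes_table,
    compare_subgroups,
    event_start_chi2,
    pearson_chi2_2x2,
    tendency_label,
)

__all__ = ["HypoglycemiaTemporalModel", "TemporalRiskResults"]


class HypoglycemiaTemporalModel:
    """Temporal hypoglycemia-risk analysis of a CGM cohort.

    Parameters
    ----------
    traces
        One :class:`~cgmrisk.io.GlucoseTrace` per patient, normalised to
        mmol/L.
    metadata
        Optional :class:`~cgmrisk.io.PatientRecord` list; enables subgroup
        comparisons.
    detection
        Episode-detection parameters (threshold, epoch, gap rule).
    windows
        Clock windows to summarise; defaults to the 03:00-07:00 early-hours
        window.
    thresholds
        Optional list of hypoglycemia cutoffs for a sensitivity sweep.
    groupings
        Metadata groupings to compare (subset of
        ``{"age", "mutation", "medication", "diagnosis"}``).
    """

    def __init__(
        self,
        traces: Sequence[cio.GlucoseTrace],
        metadata: Sequence[cio.PatientRecord] | None = None,
        detection: DetectionConfig | None = None,
        windows: Sequence[ClockWindow] = (EARLY_HOURS,),
        thresholds: Sequence[float] | None = None,
        groupings: Sequence[str] = ("age", "mutation", "medication"),
    ) -> None:
        if not traces:
            raise ValueError("no traces")
        ids = [t.patient_id for t in traces]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id among traces")
        if not windows:
            raise ValueError("at least one clock window is required")
        self.traces = list(traces)
        self.metadata = list(metadata) if metadata else None
        self.detection = detection or DetectionConfig()
        self.windows = list(windows)
        self.thresholds = list(thresholds) if thresholds else None
        self.groupings = list(groupings)

    @classmethod
    def from_csv(
        cls,
        trace_paths: Sequence[str | Path],
        metadata_path: str | Path | None = None,
        exclusions_path: str | Path | None = None,
        dialect: str = "normalized",
        units: str = "auto",
        **kwargs,
    ) -> "HypoglycemiaTemporalModel":
        """Build the model from normalized/CLARITY CSV files, applying any
        exclusion intervals (e.g. in-hospital controlled fasts)."""
        traces = [
            cio.parse_cgm_csv(p, dialect=dialect, units=units) for p in trace_paths
        ]
        if exclusions_path is not None:
            exclusions = cio.read_exclusions_csv(exclusions_path)
            traces = [cio.exclude_intervals(t, exclusions) for t in traces]
            traces = [t for t in traces if t.n_readings > 0]
        metadata = (
            cio.read_metadata_csv(metadata_path) if metadata_path is not None else None
        )
        return cls(traces, metadata=metadata, **kwargs)

    def fit(self) -> "TemporalRiskResults":
        """Run detection, profiling, testing and (optionally) the sweep."""
        events = {t.patient_id: detect_events(t, self.detection) for t in self.traces}
        stats = cohort_event_stats(events, self.traces, self.detection)
        profile = minutes_by_hour(self.traces, events, self.detection)

        summaries: dict[str, WindowSummary] = {}
        minute_tests: dict[str, TestResult | None] = {}
        event_tests: dict[str, TestResult | None] = {}
        for w in self.windows:
            key = w.label or str(w)
            s = window_summary(profile, w)
            summaries[key] = s
            minute_tests[key] = (
                pearson_chi2_2x2(build_minutes_table(s)) if s.total_hypo > 0 else None
            )
            event_tests[key] = (
                event_start_chi2(profile, w) if profile.total_events > 0 else None
            )

        subgroups: dict[str, SubgroupComparison] = {}
        if self.metadata is not None:
            for grouping in self.groupings:
                subgroups[grouping] = compare_subgroups(
                    self.traces, events, self.metadata, grouping,
                    self.windows[0], self.detection,
                )

        sweep = None
        if self.thresholds:
            sweep = threshold_sweep(
                self.traces, self.thresholds, self.windows[0], self.detection
            )

        return TemporalRiskResults(
            model=self,
            events_by_patient=events,
            cohort_stats=stats,
            hourly_profile=profile,
            window_summaries=summaries,
            minute_tests=minute_tests,
            event_tests=event_tests,
            subgroups=subgroups,
            sweep=sweep,
        )


@dataclass
class TemporalRiskResults:
    """Fitted cohort analysis: events, profiles, window tests, subgroups."""

    model: HypoglycemiaTemporalModel
    events_by_patient: dict[str, list[HypoEvent]]
    cohort_stats: CohortEventStats
    hourly_profile: HourlyProfile
    window_summaries: dict[str, WindowSummary]
    minute_tests: dict[str, TestResult | None]
    event_tests: dict[str, TestResult | None]
    subgroups: dict[str, SubgroupComparison]
    sweep: ThresholdSweepResult | None = None

    @property
    def events(self) -> list[HypoEvent]:
        return [e for evs in self.events_by_patient.values() for e in evs]

    def prolonged_events(self) -> list[HypoEvent]:
        return filter_prolonged(self.events, self.model.detection)

    def summary(self) -> str:
        """Human-readable cohort report (percentages half-up rounded:
        1 dp for prose-style rates, 2 dp for shares)."""
        s = self.cohort_stats
        det = self.model.detection
        lines = [
            "Hypoglycemia temporal risk analysis",
            "=" * 51,
            f"Patients:                 {len(self.model.traces)}",
            f"Threshold:                < {det.threshold} mmol/L",
            f"Monitored minutes:        {s.total_monitored_minutes:,.0f}",
            f"Hypoglycemic minutes:     {s.total_hypo_minutes:,.0f}"
            f" ({round_half_up(s.percent_time_hypo, 1)}%)",
            f"Events:                   {s.n_events}"
            f" (mean {round_half_up(s.mean_events_per_patient, 1)}/patient,"
            f" SD {round_half_up(s.sd_events_per_patient, 1)})",
            f"Event duration (min):     mean {round_half_up(s.mean_duration, 0):.0f},"
            f" SD {round_half_up(s.sd_duration, 0):.0f}"
            if s.n_events else "Event duration (min):     n/a",
            f"Event nadir (mmol/L):     mean {round_half_up(s.mean_nadir, 1)},"
            f" SD {round_half_up(s.sd_nadir, 2)}"
            if s.n_events else "Event nadir (mmol/L):     n/a",
            f"Prolonged events (>{det.prolonged_minutes:.0f} min): {s.n_prolonged}",
            "",
        ]
        for key, summ in self.window_summaries.items():
            lines.append(f"Window {key} [{summ.window}]")
            lines.append(
                f"  inside:  {summ.inside_hypo:,.0f}/{summ.inside_monitored:,.0f} min"
                f" ({round_half_up(summ.inside_percent, 1)}%)"
            )
            lines.append(
                f"  outside: {summ.outside_hypo:,.0f}/{summ.outside_monitored:,.0f} min"
                f" ({round_half_up(summ.outside_percent, 1)}%)"
            )
            share = summ.hypo_share_inside
            share_txt = "n/a" if np.isnan(share) else f"{round_half_up(share, 2)}%"
            lines.append(
                f"  hypo-minute share inside: {share_txt}"
                f" (expected {round_half_up(summ.expected_share, 1)}%)"
            )
            rr = summ.risk_ratio
            lines.append(
                f"  risk ratio: {'n/a' if np.isnan(rr) else round_half_up(rr, 2)}"
                f"   tendency: {tendency_label(summ)}"
            )
            mt, et = self.minute_tests.get(key), self.event_tests.get(key)
            if mt:
                lines.append(
                    f"  minute chi2(1) = {mt.statistic:.1f}, p = {mt.p_value:.3g}"
                )
            if et:
                lines.append(
                    f"  event-start chi2(1) = {et.statistic:.1f}, p = {et.p_value:.3g}"
                )
            lines.append("")
        for grouping, comp in self.subgroups.items():
            lines.append(f"Subgroups by {grouping} ({comp.window.label or comp.window})")
            for name, g in comp.groups.items():
                summ = g["summary"]
                if summ is None or np.isnan(summ.hypo_share_inside):
                    lines.append(f"  {name}: n={g['n_patients']}, no hypoglycemia")
                    continue
                lines.append(
                    f"  {name}: n={g['n_patients']},"
                    f" inside {round_half_up(summ.inside_percent, 2)}%"
                    f" vs outside {round_half_up(summ.outside_percent, 2)}%,"
                    f" share {round_half_up(summ.hypo_share_inside, 2)}%"
                    f" -> {g['tendency']}"
                )
            lines.append("")
        if self.sweep is not None:
            lines.append("Threshold sweep")
            for th in self.sweep.thresholds:
                summ = self.sweep.summaries[th]
                share = summ.hypo_share_inside
                share_txt = "n/a" if np.isnan(share) else f"{round_half_up(share, 0):.0f}%"
                lines.append(
                    f"  < {th} mmol/L: {self.sweep.n_events[th]} events,"
                    f" {self.sweep.total_hypo_minutes[th]:,.0f} hypo min,"
                    f" share inside {share_txt}"
                )
            lines.append("")
        return "\n".join(lines)

    def plot_hourly(self, ax=None, highlight: ClockWindow | None = None):
        """Bar chart of percent time hypoglycemic by clock hour; bars inside
        the highlighted window (default: the model's first window) are
        drawn darker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        highlight = highlight or self.model.windows[0]
        pct = np.nan_to_num(self.hourly_profile.percent, nan=0.0)
        colors = [
            "#1f3d7a" if highlight.contains(h) else "#9db5dc" for h in range(24)
        ]
        ax.bar(np.arange(24), pct, color=colors)
        ax.set_xlabel("hour of day")
        ax.set_ylabel("% time hypoglycemic")
        ax.set_xticks(range(0, 24, 3))
        return ax

    def plot_event_starts(self, ax=None, highlight: ClockWindow | None = None):
        """Bar chart of event counts by start hour."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        highlight = highlight or self.model.windows[0]
        colors = [
            "#333333" if highlight.contains(h) else "#aaaaaa" for h in range(24)
        ]
        ax.bar(np.arange(24), self.hourly_profile.event_starts, color=colors)
        ax.set_xlabel("hour of day")
        ax.set_ylabel("events starting")
        ax.set_xticks(range(0, 24, 3))
        return ax
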