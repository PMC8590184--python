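"""Full-pipeline orchestration: a RunConfig (YAML-loadable) drives parsing,
exclusion, detection, profiling, subgroup comparison and the threshold
sweep, writing a deterministic report bundle.

Outputs carry the SHA-256 hash of the canonicalised configuration so any
bundle can be traced to the exact settings that produced it; no wall-clock
timestamps are written, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .events import DetectionConfig, write_events_csv
from .io import read_exclusions_csv, read_metadata_csv, parse_cgm_csv, exclude_intervals
from .model import HypoglycemiaTemporalModel
from .profiles import ClockWindow, EARLY_HOURS, round_half_up
from .stats import tendency_label

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    trace_paths: list[str]
    out_dir: str
    metadata_path: str | None = None
    exclusions_path: str | None = None
    dialect: str = "normalized"
    units: str = "auto"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    windows: list[ClockWindow] = field(default_factory=lambda: [EARLY_HOURS])
    thresholds: list[float] | None = None
    groupings: list[str] = field(default_factory=lambda: ["age", "mutation", "medication"])
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("at least one window is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = DetectionConfig(**raw.pop("detection", {}))
        windows = [
            ClockWindow.from_string(w) if isinstance(w, str)
            else ClockWindow(**w)
            for w in raw.pop("windows", ["03:00-07:00"])
        ]
        return cls(detection=det, windows=windows, **raw)

    def to_canonical_dict(self) -> dict:
        return {
            "trace_paths": list(self.trace_paths),
            "metadata_path": self.metadata_path,
            "exclusions_path": self.exclusions_path,
            "dialect": self.dialect,
            "units": self.units,
            "detection": {
                "threshold": self.detection.threshold,
                "epoch_minutes": self.detection.epoch_minutes,
                "max_gap_minutes": self.detection.max_gap_minutes,
                "prolonged_minutes": self.detection.prolonged_minutes,
            },
            "windows": [str(w) for w in self.windows],
            "thresholds": self.thresholds,
            "groupings": list(self.groupings),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline and write the report bundle.

    Returns a mapping of artefact name to path. Raises before writing
    anything if there are no traces; any stage error propagates with the
    stage name and patient context attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.trace_paths:
        raise ValueError("no traces")

    traces = []
    for p in config.trace_paths:
        try:
            traces.append(
                parse_cgm_csv(p, dialect=config.dialect, units=config.units)
            )
        except Exception as exc:
            raise RuntimeError(f"stage=parse file={p}: {exc}") from exc
    if config.exclusions_path:
        exclusions = read_exclusions_csv(config.exclusions_path)
        traces = [exclude_intervals(t, exclusions) for t in traces]
        traces = [t for t in traces if t.n_readings > 0]
        if not traces:
            raise ValueError("no traces remain after exclusions")
    metadata = read_metadata_csv(config.metadata_path) if config.metadata_path else None

    model = HypoglycemiaTemporalModel(
        traces,
        metadata=metadata,
        detection=config.detection,
        windows=config.windows,
        thresholds=config.thresholds,
        groupings=config.groupings if metadata else (),
    )
    results = model.fit()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "version": __version__}
    artefacts: dict[str, Path] = {}

    def _write_json(name: str, payload: dict) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump({**stamp, **payload}, fh, indent=1, sort_keys=True)
        artefacts[name] = path

    events_path = out / "events.csv"
    write_events_csv(results.events, events_path)
    artefacts["events.csv"] = events_path

    profile_path = out / "hourly_profile.csv"
    results.hourly_profile.to_dataframe().to_csv(
        profile_path, index=False, float_format="%.4f"
    )
    artefacts["hourly_profile.csv"] = profile_path

    windows_payload = {}
    for key, summ in results.window_summaries.items():
        entry = summ.to_dict()
        entry["tendency"] = tendency_label(summ)
        mt = results.minute_tests.get(key)
        et = results.event_tests.get(key)
        if mt:
            entry["minutes_chi2"] = {"statistic": mt.statistic, "p_value": mt.p_value}
        if et:
            entry["event_chi2"] = {"statistic": et.statistic, "p_value": et.p_value}
        windows_payload[key] = entry
    _write_json("window_summaries.json", {"windows": windows_payload})

    s = results.cohort_stats
    _write_json(
        "cohort_stats.json",
        {
            "n_patients": len(traces),
            "n_events": s.n_events,
            "total_hypo_minutes": s.total_hypo_minutes,
            "total_monitored_minutes": s.total_monitored_minutes,
            "percent_time_hypo": s.percent_time_hypo,
            "mean_duration": s.mean_duration,
            "sd_duration": s.sd_duration,
            "mean_nadir": s.mean_nadir,
            "sd_nadir": s.sd_nadir,
            "mean_events_per_patient": s.mean_events_per_patient,
            "sd_events_per_patient": s.sd_events_per_patient,
            "n_prolonged": s.n_prolonged,
            "mean_prolonged_duration": s.mean_prolonged_duration,
            "mean_prolonged_nadir": s.mean_prolonged_nadir,
            "per_patient_counts": s.per_patient_counts,
        },
    )

    if results.subgroups:
        _write_json(
            "subgroups.json",
            {"comparisons": {k: v.to_dict() for k, v in results.subgroups.items()}},
        )

    if results.sweep is not None:
        sweep = results.sweep
        _write_json(
            "threshold_sweep.json",
            {
                "window": str(sweep.window),
                "thresholds": sweep.thresholds,
                "results": {
                    str(th): {
                        "n_events": sweep.n_events[th],
                        "total_hypo_minutes": sweep.total_hypo_minutes[th],
                        "summary": sweep.summaries[th].to_dict(),
                    }
                    for th in sweep.thresholds
                },
            },
        )

    report_path = out / "report.md"
    with open(report_path, "w") as fh:
        fh.write(f"# CGM hypoglycemia temporal risk report\n\n")
        fh.write(f"- config hash: `{stamp['config_hash']}`\n")
        fh.write(f"- cgmrisk version: {__version__}\n\n")
        fh.write("```\n")
        fh.write(results.summary())
        fh.write("```\n")
    artefacts["report.md"] = report_path

    _write_json("run_config.json", {"config": config.to_canonical_dict()})
    return artefacts
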