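from datetime import timedelta

import numpy as np
import pytest

from cgmrisk.events import (
    DetectionConfig,
    cohort_event_stats,
    detect_events,
    filter_prolonged,
)

from conftest import make_trace, random_trace


def brute_force_events(trace, config):
    """Independent oracle: enumerate maximal below-threshold runs directly,
    splitting whenever the inter-reading gap exceeds the limit."""
    runs, current = [], []
    for r in trace.readings:
        if r.value >= config.threshold:
            if current:
                runs.append(current)
                current = []
            continue
        if current:
            gap = (r.timestamp - current[-1].timestamp).total_seconds() / 60
            if gap > config.max_gap_minutes:
                runs.append(current)
                current = []
        current.append(r)
    if current:
        runs.append(current)
    return [
        (run[0].timestamp, run[-1].timestamp, len(run), min(x.value for x in run))
        for run in runs
    ]


class TestDetect:
    def test_no_events_at_or_above_threshold(self):
        trace = make_trace([3.5, 4.0, 5.0])  # 3.5 is not hypoglycemic (strict <)
        assert detect_events(trace, DetectionConfig()) == []

    def test_single_reading_event(self):
        trace = make_trace([3.4], start="2023-03-06T04:00")
        (event,) = detect_events(trace, DetectionConfig())
        assert event.start == event.end
        assert event.duration_minutes == 5
        assert event.nadir == 3.4

    def test_two_runs(self):
        values = [5, 5, 3.4, 3.3, 3.4, 5, 5, 3.2, 5, 5, 5, 5]
        events = detect_events(make_trace(values), DetectionConfig())
        assert [e.duration_minutes for e in events] == [15, 5]
        assert [e.nadir for e in events] == [3.3, 3.2]

    def test_gap_splits_run(self):
        trace = make_trace([3.4, 3.4], start="2023-03-06T04:00", step_minutes=20)
        events = detect_events(trace, DetectionConfig())
        assert [e.duration_minutes for e in events] == [5, 5]

    def test_gap_within_limit_continues_run(self):
        cfg = DetectionConfig(max_gap_minutes=10)
        trace = make_trace([3.4, 3.3], step_minutes=10)
        events = detect_events(trace, cfg)
        assert [e.n_epochs for e in events] == [2]

    def test_clipped_low_counts_and_flags(self):
        trace = make_trace([2.2, 3.0], clipped=["low", ""])
        (event,) = detect_events(trace, DetectionConfig())
        assert event.nadir == 2.2
        assert event.nadir_clipped

    def test_empty_trace(self):
        trace = make_trace([])
        assert detect_events(trace, DetectionConfig()) == []

    def test_oracle_equivalence_random_traces(self, rng):
        cfg = DetectionConfig()
        for i in range(200):
            trace = random_trace(rng, patient_id=f"O{i}")
            events = detect_events(trace, cfg)
            expected = brute_force_events(trace, cfg)
            assert [
                (e.start, e.end, e.n_epochs, e.nadir) for e in events
            ] == expected

    def test_minute_conservation(self, rng):
        cfg = DetectionConfig()
        for i in range(100):
            trace = random_trace(rng, patient_id=f"C{i}")
            events = detect_events(trace, cfg)
            n_below = sum(1 for r in trace.readings if r.value < cfg.threshold)
            assert sum(e.duration_minutes for e in events) == 5 * n_below

    def test_maximality(self, rng):
        cfg = DetectionConfig()
        for i in range(100):
            trace = random_trace(rng, patient_id=f"M{i}")
            by_time = {r.timestamp: r for r in trace.readings}
            times = [r.timestamp for r in trace.readings]
            for e in detect_events(trace, cfg):
                i_start, i_end = times.index(e.start), times.index(e.end)
                if i_start > 0:
                    prev = trace.readings[i_start - 1]
                    gap = (e.start - prev.timestamp).total_seconds() / 60
                    if gap <= cfg.max_gap_minutes:
                        assert prev.value >= cfg.threshold
                if i_end < len(times) - 1:
                    nxt = trace.readings[i_end + 1]
                    gap = (nxt.timestamp - e.end).total_seconds() / 60
                    if gap <= cfg.max_gap_minutes:
                        assert nxt.value >= cfg.threshold

    def test_threshold_monotonicity_of_minutes(self, rng):
        for i in range(50):
            trace = random_trace(rng, patient_id=f"T{i}")
            minutes = []
            for th in (3.0, 3.5, 3.9):
                cfg = DetectionConfig(threshold=th)
                minutes.append(
                    sum(e.duration_minutes for e in detect_events(trace, cfg))
                )
            assert minutes == sorted(minutes)


class TestProlonged:
    def test_strict_cutoff(self):
        events = detect_events(
            make_trace([3.4] * 1 + [5] + [3.4] * 6 + [5] + [3.4] * 7),
            DetectionConfig(),
        )
        assert [e.duration_minutes for e in events] == [5, 30, 35]
        kept = filter_prolonged(events, DetectionConfig())
        assert [e.duration_minutes for e in kept] == [35]  # 30 is excluded

    def test_empty(self):
        assert filter_prolonged([], DetectionConfig()) == []

    def test_mean_of_retained(self):
        values = [3.4] * 7 + [5] + [3.4] * 16 + [5] + [3.4] * 25
        events = detect_events(make_trace(values), DetectionConfig())
        kept = filter_prolonged(events, DetectionConfig())
        assert np.mean([e.duration_minutes for e in kept]) == 80


class TestCohortStats:
    def test_percent_and_counts(self):
        t1 = make_trace([3.4, 5, 5, 5], patient_id="A")
        t2 = make_trace([5] * 4, patient_id="B")
        events = {"A": detect_events(t1, DetectionConfig()), "B": []}
        stats = cohort_event_stats(events, [t1, t2], DetectionConfig())
        assert stats.total_monitored_minutes == 40
        assert stats.total_hypo_minutes == 5
        assert stats.percent_time_hypo == pytest.approx(12.5)
        assert stats.per_patient_counts == {"A": 1, "B": 0}
        assert stats.mean_events_per_patient == 0.5

    def test_mean_count_includes_zero_patients(self):
        t1 = make_trace([3.4, 5, 3.2, 5, 3.1, 5, 3.0, 5], patient_id="A")
        t2 = make_trace([5] * 8, patient_id="B")
        events = {"A": detect_events(t1, DetectionConfig())}
        stats = cohort_event_stats(events, [t1, t2], DetectionConfig())
        assert stats.per_patient_counts["A"] == 4
        assert stats.mean_events_per_patient == 2.0

    def test_zero_monitored_is_error(self):
        trace = make_trace([])
        with pytest.raises(ValueError, match="monitored"):
            cohort_event_stats({}, [trace], DetectionConfig())

    def test_unknown_patient_is_error(self):
        t1 = make_trace([5], patient_id="A")
        with pytest.raises(ValueError, match="without traces"):
            cohort_event_stats({"Z": []}, [t1], DetectionConfig())

    def test_sample_sd(self):
        values = [3.4] * 1 + [5] + [3.4] * 3
        trace = make_trace(values, patient_id="A")
        events = {"A": detect_events(trace, DetectionConfig())}
        stats = cohort_event_stats(events, [trace], DetectionConfig())
        # durations 5 and 15: sample SD = sqrt(50)
        assert stats.sd_duration == pytest.approx(np.sqrt(50))


class TestConfigValidation:
    def test_gap_must_cover_epoch(self):
        with pytest.raises(ValueError):
            DetectionConfig(max_gap_minutes=2)

    def test_epoch_positive(self):
        with pytest.raises(ValueError):
            DetectionConfig(epoch_minutes=0)
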