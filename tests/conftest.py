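from datetime import datetime, timedelta

import numpy as np
import pytest

from cgmrisk.io import GlucoseReading, GlucoseTrace


def make_trace(values, start="2023-03-06T08:00", patient_id="P001",
               step_minutes=5, clipped=None):
    """Build a trace from glucose values at a fixed spacing."""
    t0 = datetime.strptime(start, "%Y-%m-%dT%H:%M")
    clipped = clipped or [""] * len(values)
    readings = [
        GlucoseReading(t0 + timedelta(minutes=i * step_minutes), float(v), c)
        for i, (v, c) in enumerate(zip(values, clipped))
    ]
    return GlucoseTrace(patient_id, readings)


def random_trace(rng, n_max=100, patient_id="R1", allow_gaps=True):
    """Random trace for oracle tests: values straddle the 3.5 threshold,
    timestamps 5-min spaced with occasional longer gaps."""
    n = int(rng.integers(1, n_max + 1))
    t = datetime(2023, 3, 6, 0, 0)
    readings = []
    for _ in range(n):
        value = float(np.round(rng.uniform(2.2, 6.0), 2))
        readings.append(GlucoseReading(t, value))
        step = 5
        if allow_gaps and rng.uniform() < 0.15:
            step = int(rng.choice([10, 15, 30, 120]))
        t = t + timedelta(minutes=step)
    return GlucoseTrace(patient_id, readings)


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort shared across tests (fixed seed)."""
    from cgmrisk.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_patients=8, days_range=(4, 6), seed=42)
    traces, records, truths = simulate_cohort(cfg)
    return cfg, traces, records, truths
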