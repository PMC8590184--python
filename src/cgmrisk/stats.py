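"""Statistical comparisons: 2x2 chi-square on minute counts, Mann-Whitney U
for continuous variables, and subgroup comparison builders.

The chi-square statistic is evaluated from the closed form
``N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with 1 df; the Mann-Whitney U is
computed from midranks, with exact enumeration of the permutation null when
the smaller sample has at most 8 observations and a tie-corrected normal
approximation otherwise. Both are two-sided; no multiple-testing correction
is applied.

A caution on pooled minutes: consecutive 5-minute epochs inside one
hypoglycemia event are not independent observations, so a chi-square that
counts minutes is anticonservative. ``event_start_chi2`` offers the same
windowed comparison with events as the counting unit, which is the
statistically calibrated variant; the minute-level test mirrors the
descriptive convention of pooling minutes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .events import DetectionConfig, HypoEvent
from .io import GlucoseTrace, PatientRecord
from .profiles import ClockWindow, HourlyProfile, WindowSummary, minutes_by_hour, window_summary

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "SubgroupComparison",
    "pearson_chi2_2x2",
    "mann_whitney_u",
    "build_minutes_table",
    "event_start_chi2",
    "compare_subgroups",
    "tendency_label",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups (e.g. inside/outside a clock
    window), columns hypoglycemic / not-hypoglycemic minutes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be nonnegative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> dict[str, int]:
        return {
            "row1": self.a + self.b,
            "row2": self.c + self.d,
            "col1": self.a + self.c,
            "col2": self.b + self.d,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def pearson_chi2_2x2(table: ContingencyTable2x2, correction: bool = False) -> TestResult:
    """Pearson chi-square test on a 2x2 table (df = 1).

    ``correction=True`` applies the Yates continuity correction. The
    default is uncorrected: with minute-count tables the cells are huge and
    the correction is immaterial. Degenerate margins are refused.
    """
    for name, margin in table.margins.items():
        if margin == 0:
            raise ValueError(f"degenerate margin: {name} is zero")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / denom
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="pearson_chi2",
        df=1,
        notes="yates" if correction else "",
    )


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x_i > y_j) + 0.5 * #(x_i == y_j), via midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _mwu_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled
    (midranked) values to the two samples."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    idx = range(n1 + n2)
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(idx, n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Reports U for the first sample (number of (x > y) pairs, ties counted
    half). Uses exact enumeration of the permutation distribution when
    ``min(n1, n2) <= 8``, otherwise the tie-corrected normal approximation.
    Identical constant samples give p = 1 with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _mwu_statistic(x, y)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(u, 1.0, "mann_whitney_u", notes="all values identical")

    if min(n1, n2) <= 8:
        p = _mwu_exact_p(x, y, u)
        return TestResult(u, p, "mann_whitney_u", notes="exact")

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u, 1.0, "mann_whitney_u", notes="degenerate variance")
    z = (u - n1 * n2 / 2.0) / math.sqrt(sigma2)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(u, min(1.0, p), "mann_whitney_u", notes="normal approximation, tie-corrected")


def build_minutes_table(summary: WindowSummary) -> ContingencyTable2x2:
    """Inside/outside x hypo/not-hypo minute counts from a window summary."""
    cells = (
        summary.inside_hypo,
        summary.inside_monitored - summary.inside_hypo,
        summary.outside_hypo,
        summary.outside_monitored - summary.outside_hypo,
    )
    if min(cells) < 0:
        raise ValueError("inconsistent summary: negative derived cell")
    return ContingencyTable2x2(*(int(round(c)) for c in cells))


def event_start_chi2(profile: HourlyProfile, window: ClockWindow) -> TestResult:
    """Goodness-of-fit chi-square on event-start counts inside vs outside a
    window, with expected counts proportional to monitored minutes.

    Events are the approximately independent units of a windowed comparison
    (every epoch of one event shares the event's start hour), so unlike the
    minute-count chi-square this test holds its nominal size under a
    uniform-hazard null.
    """
    mask = np.zeros(24, dtype=bool)
    mask[list(window.hours)] = True
    obs_in = float(profile.event_starts[mask].sum())
    obs_out = float(profile.event_starts[~mask].sum())
    n = obs_in + obs_out
    if n == 0:
        raise ValueError("no events to test")
    p_in = profile.monitored_minutes[mask].sum() / profile.total_monitored
    exp_in, exp_out = n * p_in, n * (1 - p_in)
    if exp_in == 0 or exp_out == 0:
        raise ValueError("window has zero expected events")
    stat = (obs_in - exp_in) ** 2 / exp_in + (obs_out - exp_out) ** 2 / exp_out
    return TestResult(
        statistic=float(stat),
        p_value=float(sps.chi2.sf(stat, df=1)),
        method="event_start_chi2",
        df=1,
        notes=f"n_events={int(n)}, expected_inside={exp_in:.1f}",
    )


def tendency_label(summary: WindowSummary) -> str:
    """Qualitative tendency of hypoglycemia toward the window.

    Banding convention (a reporting convenience, not an inferential claim):
    risk ratio >= 3 -> "++" (very strong), >= 2 -> "+", >= 1.5 -> "-",
    >= 1 -> "--"; a ratio below 1.2 with a hypo-minute share within 5
    points of the expected share is "evenly distributed"; a ratio below 1
    otherwise marks the window as relatively protected.
    """
    rr = summary.risk_ratio
    share = summary.hypo_share_inside
    if math.isnan(rr) or math.isnan(share):
        return "undefined"
    if rr < 1.2 and abs(share - summary.expected_share) <= 5.0:
        return "evenly distributed"
    if rr >= 3.0:
        return "++"
    if rr >= 2.0:
        return "+"
    if rr >= 1.5:
        return "-"
    if rr >= 1.0:
        return "--"
    return "reduced risk inside"


def demographic_comparison(records: Sequence[PatientRecord]) -> dict[str, TestResult]:
    """Baseline comparison between the two diagnosis groups: chi-square on
    the sex split, Mann-Whitney U on age in months."""
    groups = sorted({r.diagnosis for r in records})
    if len(groups) != 2:
        raise ValueError("demographic comparison needs exactly two diagnosis groups")
    g1 = [r for r in records if r.diagnosis == groups[0]]
    g2 = [r for r in records if r.diagnosis == groups[1]]
    sex_table = ContingencyTable2x2(
        sum(r.sex == "male" for r in g1), sum(r.sex == "female" for r in g1),
        sum(r.sex == "male" for r in g2), sum(r.sex == "female" for r in g2),
    )
    return {
        "sex": pearson_chi2_2x2(sex_table),
        "age_months": mann_whitney_u(
            [r.age_months for r in g1], [r.age_months for r in g2]
        ),
    }


_GROUPERS = {
    "age": lambda r: "age >= 10 months" if r.age_months >= 10 else "age < 10 months",
    "mutation": lambda r: "positive" if r.mutation_positive else "negative/unknown",
    "medication": lambda r: "on" if r.on_medication else "off",
    "diagnosis": lambda r: r.diagnosis,
}


@dataclass
class SubgroupComparison:
    """Per-group window summaries with chi-square tests and tendency labels."""

    grouping: str
    window: ClockWindow
    groups: dict[str, dict]

    def to_dict(self) -> dict:
        out = {"grouping": self.grouping, "window": str(self.window), "groups": {}}
        for name, g in self.groups.items():
            entry = {
                "n_patients": g["n_patients"],
                "tendency": g["tendency"],
            }
            if g["summary"] is not None:
                entry["summary"] = g["summary"].to_dict()
            if g["minutes_chi2"] is not None:
                t = g["minutes_chi2"]
                entry["minutes_chi2"] = {"statistic": t.statistic, "p_value": t.p_value}
            if g["event_chi2"] is not None:
                t = g["event_chi2"]
                entry["event_chi2"] = {"statistic": t.statistic, "p_value": t.p_value}
            out["groups"][name] = entry
        return out


def compare_subgroups(
    traces: Sequence[GlucoseTrace],
    events_by_patient: Mapping[str, Sequence[HypoEvent]],
    records: Sequence[PatientRecord],
    grouping: str,
    window: ClockWindow,
    config: DetectionConfig | None = None,
) -> SubgroupComparison:
    """Split the cohort by a metadata label and compare the clock window
    within each group.

    Supported groupings: ``age`` (split at 10 months, older = >= 10),
    ``mutation`` (positive vs negative/unknown — untested patients count
    with negative), ``medication`` (on = any treatment listed), and
    ``diagnosis`` (HI vs IKH). Each group gets a WindowSummary, the
    minute-count and event-start chi-square tests, and a tendency label;
    empty groups are reported with zero minutes and no test.
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"unknown grouping {grouping!r}; use one of {sorted(_GROUPERS)}")
    by_id = {r.patient_id: r for r in records}
    missing = [t.patient_id for t in traces if t.patient_id not in by_id]
    if missing:
        raise ValueError(f"traces without metadata: {missing}")
    grouper = _GROUPERS[grouping]
    config = config or DetectionConfig()

    assignments: dict[str, list[GlucoseTrace]] = {}
    for t in traces:
        assignments.setdefault(grouper(by_id[t.patient_id]), []).append(t)

    groups: dict[str, dict] = {}
    for name in sorted(assignments):
        members = assignments[name]
        evs = {t.patient_id: events_by_patient.get(t.patient_id, []) for t in members}
        profile = minutes_by_hour(members, evs, config)
        entry: dict = {
            "n_patients": len(members),
            "profile": profile,
            "summary": None,
            "minutes_chi2": None,
            "event_chi2": None,
            "tendency": "undefined",
        }
        if profile.total_monitored > 0:
            summary = window_summary(profile, window)
            entry["summary"] = summary
            entry["tendency"] = tendency_label(summary)
            if summary.total_hypo > 0:
                entry["minutes_chi2"] = pearson_chi2_2x2(build_minutes_table(summary))
                if profile.total_events > 0:
                    entry["event_chi2"] = event_start_chi2(profile, window)
        groups[name] = entry
    return SubgroupComparison(grouping=grouping, window=window, groups=groups)
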