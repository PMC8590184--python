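import math

import numpy as np
import pytest
from scipy import stats as sps

from cgmrisk.events import DetectionConfig, detect_events
from cgmrisk.profiles import EARLY_HOURS, summary_from_counts
from cgmrisk.simulate import SimulationConfig, simulate_cohort
from cgmrisk.stats import (
    ContingencyTable2x2,
    build_minutes_table,
    compare_subgroups,
    demographic_comparison,
    event_start_chi2,
    mann_whitney_u,
    pearson_chi2_2x2,
    tendency_label,
)


def chi2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def brute_force_u(x, y):
    """Pair-counting oracle: #(x > y) + 0.5 #(x == y)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestChi2:
    def test_equal_proportions_zero(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0
        assert res.p_value == 1

    def test_identical_rates_zero(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(10, 90, 20, 180))
        assert res.statistic == pytest.approx(0, abs=1e-12)

    def test_closed_form_agreement(self):
        table = ContingencyTable2x2(5, 5, 1, 9)
        res = pearson_chi2_2x2(table)
        assert res.statistic == pytest.approx(chi2_closed_form(5, 5, 1, 9))

    def test_against_scipy(self, rng):
        # independent implementation cross-check, with and without Yates
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, size=4)
            table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            for correction in (False, True):
                ours = pearson_chi2_2x2(table, correction=correction)
                ref = sps.chi2_contingency(
                    [[a, b], [c, d]], correction=correction
                )
                assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
                assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_transposition_and_swap_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(1, 100, size=4))
            base = pearson_chi2_2x2(ContingencyTable2x2(a, b, c, d)).statistic
            transposed = pearson_chi2_2x2(ContingencyTable2x2(a, c, b, d)).statistic
            rows_swapped = pearson_chi2_2x2(ContingencyTable2x2(c, d, a, b)).statistic
            assert base == pytest.approx(transposed)
            assert base == pytest.approx(rows_swapped)

    def test_linear_scaling(self):
        base = pearson_chi2_2x2(ContingencyTable2x2(5, 5, 1, 9)).statistic
        scaled = pearson_chi2_2x2(ContingencyTable2x2(50, 50, 10, 90)).statistic
        assert scaled == pytest.approx(10 * base)

    def test_zero_margin_refused(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2_2x2(ContingencyTable2x2(0, 10, 0, 10))

    def test_negative_cell_refused(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5
        assert res.p_value == 1

    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [10, 20])
        assert res.statistic == 0

    def test_constant_samples_note(self):
        res = mann_whitney_u([5, 5], [5, 5, 5])
        assert res.p_value == 1
        assert "identical" in res.notes

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(1, 9, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 6, size=n2).astype(float)
            res = mann_whitney_u(x, y)
            assert res.statistic == pytest.approx(brute_force_u(x, y))

    def test_u_symmetry(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=9)
            ux = mann_whitney_u(x, y).statistic
            uy = mann_whitney_u(y, x).statistic
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        base = mann_whitney_u(x, y)
        trans = mann_whitney_u(np.exp(x), np.exp(y))
        assert base.statistic == trans.statistic
        assert base.p_value == trans.p_value

    def test_exact_p_against_scipy_no_ties(self, rng):
        # scipy's exact method is the independent reference when tie-free
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_against_scipy(self, rng):
        x = rng.integers(0, 10, size=15).astype(float)
        y = rng.integers(0, 10, size=20).astype(float)
        ours = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_refused(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestMinutesTable:
    def test_published_cells(self):
        s = summary_from_counts(EARLY_HOURS, 1665, 25_875, 3585, 123_490)
        t = build_minutes_table(s)
        assert (t.a, t.b, t.c, t.d) == (1665, 24_210, 3585, 119_905)

    def test_zero_hypo_column_refused_in_test(self):
        s = summary_from_counts(EARLY_HOURS, 0, 100, 0, 500)
        t = build_minutes_table(s)
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2_2x2(t)

    def test_equal_rates_statistic_zero(self):
        s = summary_from_counts(EARLY_HOURS, 5, 10, 5, 10)
        res = pearson_chi2_2x2(build_minutes_table(s))
        assert res.statistic == pytest.approx(0)


class TestTendency:
    @pytest.mark.parametrize(
        "inside,outside,expected",
        [
            ((350, 1000), (1000, 10_000), "++"),      # rr = 3.5
            ((250, 1000), (1000, 10_000), "+"),       # rr = 2.5
            ((170, 1000), (1000, 10_000), "-"),       # rr = 1.7
            ((130, 1000), (1000, 10_000), "--"),      # rr = 1.3
            ((50, 1000), (1000, 10_000), "reduced risk inside"),
        ],
    )
    def test_bands(self, inside, outside, expected):
        s = summary_from_counts(EARLY_HOURS, inside[0], inside[1], outside[0], outside[1])
        assert tendency_label(s) == expected

    def test_evenly_distributed(self):
        # 1/6 of monitored time and 1/6 of hypo minutes inside, rr = 1
        s = summary_from_counts(EARLY_HOURS, 100, 1000, 500, 5000)
        assert tendency_label(s) == "evenly distributed"


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_patients=10, days_range=(4, 5), seed=99)
    traces, records, _ = simulate_cohort(cfg)
    det = DetectionConfig()
    events = {t.patient_id: detect_events(t, det) for t in traces}
    return traces, events, records


class TestSubgroups:
    @pytest.mark.parametrize("grouping", ["age", "mutation", "medication"])
    def test_partition_reconciles(self, cohort, grouping):
        traces, events, records = cohort
        comp = compare_subgroups(traces, events, records, grouping, EARLY_HOURS)
        total_mon = sum(t.monitored_minutes for t in traces)
        got_mon = sum(
            g["profile"].total_monitored for g in comp.groups.values()
        )
        got_hypo = sum(g["profile"].total_hypo for g in comp.groups.values())
        all_hypo = 5 * sum(
            1 for t in traces for r in t.readings if r.value < 3.5
        )
        assert got_mon == total_mon
        assert got_hypo == all_hypo

    def test_unknown_grouping(self, cohort):
        traces, events, records = cohort
        with pytest.raises(ValueError, match="grouping"):
            compare_subgroups(traces, events, records, "shoe-size", EARLY_HOURS)

    def test_missing_metadata(self, cohort):
        traces, events, records = cohort
        with pytest.raises(ValueError, match="metadata"):
            compare_subgroups(traces, events, records[:-1], "age", EARLY_HOURS)

    def test_to_dict_is_serialisable(self, cohort):
        import json

        traces, events, records = cohort
        comp = compare_subgroups(traces, events, records, "medication", EARLY_HOURS)
        json.dumps(comp.to_dict())


class TestDemographics:
    def test_two_group_comparison(self):
        from cgmrisk.datasets import reference_hi_records
        from cgmrisk.io import PatientRecord

        rng = np.random.default_rng(0)
        ikh = [
            PatientRecord(f"IKH{i:02d}", "IKH", "male" if i < 12 else "female",
                          int(rng.integers(12, 160)))
            for i in range(24)
        ]
        res = demographic_comparison(reference_hi_records() + ikh)
        assert set(res) == {"sex", "age_months"}
        # HI: 17M/6F vs IKH: 12M/12F
        expected = pearson_chi2_2x2(ContingencyTable2x2(17, 6, 12, 12))
        assert res["sex"].statistic == pytest.approx(expected.statistic)

    def test_needs_two_groups(self):
        from cgmrisk.datasets import reference_hi_records

        with pytest.raises(ValueError, match="two diagnosis"):
            demographic_comparison(reference_hi_records())


class TestEventStartChi2:
    def test_matches_gof_formula(self, rng):
        cfg = SimulationConfig(n_patients=6, days_range=(4, 4), seed=5)
        traces, _, _ = simulate_cohort(cfg)
        det = DetectionConfig()
        events = {t.patient_id: detect_events(t, det) for t in traces}
        from cgmrisk.profiles import minutes_by_hour

        profile = minutes_by_hour(traces, events, det)
        res = event_start_chi2(profile, EARLY_HOURS)
        n = profile.total_events
        p_in = (
            profile.monitored_minutes[[3, 4, 5, 6]].sum() / profile.total_monitored
        )
        obs_in = profile.event_starts[[3, 4, 5, 6]].sum()
        exp_in, exp_out = n * p_in, n * (1 - p_in)
        stat = (obs_in - exp_in) ** 2 / exp_in + ((n - obs_in) - exp_out) ** 2 / exp_out
        assert res.statistic == pytest.approx(stat)
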