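"""Reference minute counts and demographics from a published pediatric
hyperinsulinism CGM cohort (23 HI + 24 IKH patients), used as worked
examples: the printed contingency totals are self-contained arithmetic that
the window-summary and cohort-statistics operations must reproduce.
"""

from __future__ import annotations

from .io import PatientRecord
from .profiles import ClockWindow, EARLY_HOURS

__all__ = [
    "REFERENCE_COUNTS",
    "reference_hi_records",
    "EVENING_LOW_RISK",
]

#: Low-risk evening window reported for the ketotic-hypoglycemia contrast
#: cohort: 6 PM to 1 AM (wraps midnight, width 7 h).
EVENING_LOW_RISK = ClockWindow(18, 1, label="evening low risk")

#: Published cohort-level minute counts (all values in minutes unless noted).
REFERENCE_COUNTS = {
    # whole cohort
    "total_hypo_minutes": 15_610,
    "total_monitored_minutes": 342_355,
    "n_events": 449,
    # HI cohort, early hours (03:00-07:00) vs rest of day
    "hi_inside_hypo": 1_665,
    "hi_inside_monitored": 25_875,
    "hi_outside_hypo": 3_585,
    "hi_outside_monitored": 123_490,
    # HI patients >= 10 months old
    "hi_over10_inside_hypo": 1_480,
    "hi_over10_inside_monitored": 19_370,
    "hi_over10_outside_hypo": 2_405,
    "hi_over10_outside_monitored": 92_840,
    # HI medication subgroups (early-hours share of all hypo minutes)
    "offmed_inside_hypo": 875,
    "offmed_total_hypo": 2_065,
    "onmed_inside_hypo": 790,
    "onmed_total_hypo": 3_185,
    # mutation subgroups
    "mutpos_inside_hypo": 1_135,
    "mutpos_inside_monitored": 17_005,
    # threshold sweep at 3.0 mmol/L (HI >= 10 months)
    "sweep30_inside_hypo": 63,
    "sweep30_total_hypo": 152,
    # IKH evening low-risk window (18:00-01:00)
    "ikh_inside_hypo": 1_575,
    "ikh_inside_monitored": 57_195,
    "ikh_outside_hypo": 8_785,
    "ikh_outside_monitored": 135_805,
}

# (sex, mutation, hi_type, surgery, age_months, location, medication)
_HI_TABLE = [
    ("male", "not-done", "diffuse", "none", 88, "outpatient", ()),
    ("male", "not-done", "diffuse", "none", 8, "outpatient", ()),
    ("female", "negative", "diffuse", "none", 92, "outpatient", ()),
    ("male", "positive:SLC16A1", "diffuse", "none", 34, "outpatient", ("carbohydrate",)),
    ("male", "positive:SLC16A1", "diffuse", "none", 37, "outpatient", ("carbohydrate",)),
    ("female", "negative", "diffuse", "none", 119, "outpatient", ()),
    ("male", "positive:ABCC8", "diffuse", "none", 58, "outpatient", ("diazoxide",)),
    ("male", "positive:GCK", "diffuse", "none", 190, "outpatient", ("diazoxide",)),
    ("male", "positive:ABCC8", "diffuse", "subtotal", 141, "outpatient", ()),
    ("male", "positive:ABCC8", "diffuse", "subtotal", 132, "outpatient", ()),
    ("male", "positive:ABCC8", "focal", "lesionectomy", 2, "inpatient", ("octreotide",)),
    ("male", "positive:ABCC8", "diffuse", "none", 36, "outpatient", ()),
    ("female", "positive:ABCC8", "diffuse", "subtotal", 51, "outpatient", ("octreotide",)),
    ("male", "positive:ABCC8", "focal", "lesionectomy", 36, "outpatient", ("octreotide",)),
    ("female", "negative", "diffuse", "none", 17, "outpatient", ("diazoxide",)),
    ("female", "positive:ABCC8", "focal", "lesionectomy", 3, "inpatient", ("octreotide",)),
    ("male", "negative", "diffuse", "none", 63, "outpatient", ("diazoxide",)),
    ("male", "negative", "diffuse", "none", 10, "outpatient", ("diazoxide",)),
    ("male", "positive:ABCC8", "diffuse", "subtotal", 193, "outpatient", ()),
    ("male", "positive:ABCC8", "focal", "lesionectomy", 1, "inpatient", ()),
    ("male", "positive:ABCC8", "focal", "lesionectomy", 3, "inpatient", ("octreotide",)),
    ("female", "positive:ABCC8", "focal", "lesionectomy", 1, "inpatient", ("octreotide",)),
    ("male", "positive:ABCC8", "focal", "lesionectomy", 3, "inpatient", ("octreotide",)),
]


def reference_hi_records() -> list[PatientRecord]:
    """The 23 hyperinsulinism patients' characteristics as PatientRecords."""
    return [
        PatientRecord(
            patient_id=f"HI{i + 1:02d}",
            diagnosis="HI",
            sex=sex,
            age_months=age,
            mutation=mutation,
            hi_type=hi_type,
            surgery=surgery,
            medication=medication,
            location=location,
        )
        for i, (sex, mutation, hi_type, surgery, age, location, medication)
        in enumerate(_HI_TABLE)
    ]
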