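import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from efminer.subtyping import (
    assign_subtype,
    build_cohort,
    compute_egfr,
    pair_probnp,
)
from efminer.types import (
    Analyte,
    DomainError,
    EFMeasurement,
    LabResult,
    RegistryRecord,
    Sex,
    Subtype,
)


def lab(analyte, date, value, pid="p1"):
    unit = "ng/l" if analyte is Analyte.PROBNP else "µmol/l"
    return LabResult(pid, dt.date.fromisoformat(date), analyte, value, unit)


def registry_row(pid="p1", sex=Sex.FEMALE, age=65.0):
    return RegistryRecord(
        patient_id=pid,
        sex=sex,
        baseline_age=age,
        hypertension=False,
        ischemic_heart_disease=False,
        type2_diabetes=False,
        copd=False,
        renal_failure=False,
        followup_entry_age=age,
        followup_exit_age=age + 1.5,
        died=False,
    )


class TestAssignSubtype:
    @pytest.mark.parametrize(
        "ef,probnp,expected",
        [
            (35.0, None, Subtype.HFREF),
            (45.0, 3000.0, Subtype.HFMREF),
            (55.0, 300.0, Subtype.HFPEF),
            (55.0, 100.0, Subtype.NOHF),
            (55.0, None, Subtype.INDETERMINATE),
            # band boundaries
            (39.999, None, Subtype.HFREF),
            (40.0, None, Subtype.HFMREF),
            (49.999, None, Subtype.HFMREF),
            (49.5, None, Subtype.HFMREF),  # non-integer daily means stay mid-range
            # biomarker threshold: exactly 125 counts as normal
            (50.0, 125.0, Subtype.NOHF),
            (50.0, 125.01, Subtype.HFPEF),
        ],
    )
    def test_rule_table(self, ef, probnp, expected):
        assert assign_subtype(ef, probnp) is expected

    @pytest.mark.parametrize("ef", [9.9, 90.5, -5.0])
    def test_out_of_domain_ef_rejected(self, ef):
        with pytest.raises(DomainError):
            assign_subtype(ef, 100.0)

    def test_probnp_ignored_below_50(self):
        for probnp in (None, 0.0, 125.0, 10000.0):
            assert assign_subtype(35.0, probnp) is Subtype.HFREF
            assert assign_subtype(45.0, probnp) is Subtype.HFMREF


def _oracle_rule(ef, probnp):
    """Independent transcription of the guideline decision table."""
    table = [
        (10.0, 40.0, "any", Subtype.HFREF),
        (40.0, 50.0, "any", Subtype.HFMREF),
        (50.0, 90.0001, "elevated", Subtype.HFPEF),
        (50.0, 90.0001, "normal", Subtype.NOHF),
        (50.0, 90.0001, "missing", Subtype.INDETERMINATE),
    ]
    if probnp is None:
        marker = "missing"
    elif probnp > 125.0:
        marker = "elevated"
    else:
        marker = "normal"
    for lo, hi, m, label in table:
        if lo <= ef < hi and m in ("any", marker):
            return label
    raise AssertionError("oracle table not exhaustive")


def test_partition_matches_independent_rule_table():
    """Brute force over the EF x proBNP grid: exactly one label everywhere."""
    probnp_grid = [None] + [float(v) for v in range(0, 5001, 125)] + [124.99, 125.0, 125.01]
    for ef10 in range(100, 901):
        ef = ef10 / 10.0
        for probnp in probnp_grid:
            got = assign_subtype(ef, probnp)
            assert got is _oracle_rule(ef, probnp), (ef, probnp)


class TestPairProbnp:
    def test_nearest_sample_wins(self):
        labs = [
            lab(Analyte.PROBNP, "2019-02-20", 200.0),
            lab(Analyte.PROBNP, "2019-04-01", 900.0),
        ]
        value, date = pair_probnp(labs, dt.date(2019, 3, 2))
        assert (value, date) == (200.0, dt.date(2019, 2, 20))

    def test_outside_window_is_missing(self):
        labs = [lab(Analyte.PROBNP, "2020-04-06", 300.0)]
        assert pair_probnp(labs, dt.date(2019, 3, 2), window_days=365) == (None, None)

    def test_equidistant_tie_prefers_earlier(self):
        labs = [
            lab(Analyte.PROBNP, "2019-03-01", 111.0),
            lab(Analyte.PROBNP, "2019-03-21", 222.0),
        ]
        value, date = pair_probnp(labs, dt.date(2019, 3, 11))
        assert (value, date) == (111.0, dt.date(2019, 3, 1))

    def test_creatinine_not_considered(self):
        labs = [lab(Analyte.CREATININE, "2019-03-02", 80.0)]
        assert pair_probnp(labs, dt.date(2019, 3, 2)) == (None, None)


class TestEGFR:
    # frozen from an independent spreadsheet-style evaluation of the
    # CKD-EPI 2009 closed form
    def test_oracle_values(self):
        assert compute_egfr(70.0, 60.0, Sex.FEMALE) == pytest.approx(81.152400, abs=1e-4)
        assert compute_egfr(80.0, 60.0, Sex.MALE) == pytest.approx(91.917243, abs=1e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        creat=st.floats(20.0, 800.0),
        age=st.floats(18.0, 100.0),
        sex=st.sampled_from([Sex.FEMALE, Sex.MALE]),
    )
    def test_doubling_creatinine_strictly_decreases(self, creat, age, sex):
        assert compute_egfr(2 * creat, age, sex) < compute_egfr(creat, age, sex)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_egfr(0.0, 60.0, Sex.FEMALE)
        with pytest.raises(DomainError):
            compute_egfr(80.0, 0.0, Sex.FEMALE)


class TestBuildCohort:
    def test_hfref_without_probnp_retained(self):
        measurements = [EFMeasurement("p1", dt.date(2019, 3, 2), 38.0, 1)]
        labs = [lab(Analyte.CREATININE, "2019-03-02", 80.0)]
        cohort, summary = build_cohort(measurements, labs, [registry_row()])
        (a,) = cohort
        assert a.subtype is Subtype.HFREF
        assert a.probnp is None
        assert summary["cohort_size"] == 1

    def test_missing_creatinine_excluded_and_counted(self):
        measurements = [EFMeasurement("p1", dt.date(2019, 3, 2), 38.0, 1)]
        cohort, summary = build_cohort(measurements, [], [registry_row()])
        assert cohort == []
        assert summary["excluded_missing_creatinine"] == 1

    def test_missing_creatinine_kept_when_not_required(self):
        measurements = [EFMeasurement("p1", dt.date(2019, 3, 2), 38.0, 1)]
        cohort, _ = build_cohort(measurements, [], [registry_row()], require_creatinine=False)
        (a,) = cohort
        assert a.egfr is None

    def test_no_ef_measurement_means_absent(self):
        cohort, summary = build_cohort([], [], [registry_row()])
        assert cohort == []
        assert summary["patients_with_ef"] == 0

    def test_normal_ef_normal_probnp_is_no_hf(self):
        measurements = [EFMeasurement("p1", dt.date(2019, 3, 2), 60.0, 1)]
        labs = [
            lab(Analyte.CREATININE, "2019-03-02", 80.0),
            lab(Analyte.PROBNP, "2019-03-10", 100.0),
        ]
        cohort, _ = build_cohort(measurements, labs, [registry_row()])
        (a,) = cohort
        assert a.subtype is Subtype.NOHF
        assert a.probnp == 100.0
        assert a.egfr == pytest.approx(compute_egfr(80.0, 65.0, Sex.FEMALE))

    def test_index_policy_latest_by_default(self):
        measurements = [
            EFMeasurement("p1", dt.date(2018, 1, 1), 30.0, 1),
            EFMeasurement("p1", dt.date(2020, 1, 1), 60.0, 1),
        ]
        labs = [
            lab(Analyte.CREATININE, "2020-01-01", 80.0),
            lab(Analyte.PROBNP, "2020-01-05", 500.0),
        ]
        cohort, _ = build_cohort(measurements, labs, [registry_row()])
        (a,) = cohort
        assert a.ef_percent == 60.0
        assert a.subtype is Subtype.HFPEF

    def test_patient_conservation(self):
        measurements = [
            EFMeasurement("p1", dt.date(2019, 3, 2), 38.0, 1),
            EFMeasurement("p2", dt.date(2019, 3, 2), 60.0, 1),
            EFMeasurement("p3", dt.date(2019, 3, 2), 45.0, 1),
        ]
        labs = [lab(Analyte.CREATININE, "2019-03-02", 80.0, pid="p1")]
        registry = [registry_row("p1"), registry_row("p2")]  # p3 unregistered
        cohort, s = build_cohort(measurements, labs, registry)
        assert s["patients_with_ef"] == 3
        assert (
            s["cohort_size"]
            == s["patients_with_ef"]
            - s["excluded_missing_registry"]
            - s["excluded_missing_creatinine"]
        )
        assert len(cohort) == s["cohort_size"] == 1
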