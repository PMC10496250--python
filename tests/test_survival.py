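import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from efminer.survival import (
    DEFAULT_COVARIATES,
    SUBTYPE_TERMS,
    _scaled_schoenfeld,
    fit_cox,
    prepare_survival,
    schoenfeld_check,
)
from efminer.synth import GenConfig, cohort_survival_frame, generate_corpus
from efminer.types import (
    DomainError,
    RegistryRecord,
    Sex,
    Subtype,
    SubtypeAssignment,
)


def assignment(pid, subtype, ef=35.0, egfr=90.0):
    return SubtypeAssignment(
        patient_id=pid, subtype=subtype, ef_percent=ef, ef_date=dt.date(2019, 1, 1), egfr=egfr
    )


def registry_row(pid, entry=65.0, exit_=66.5, died=False, sex=Sex.FEMALE):
    return RegistryRecord(
        patient_id=pid,
        sex=sex,
        baseline_age=entry,
        hypertension=False,
        ischemic_heart_disease=False,
        type2_diabetes=False,
        copd=False,
        renal_failure=False,
        followup_entry_age=entry,
        followup_exit_age=exit_,
        died=died,
    )


class TestPrepareSurvival:
    def test_reference_coding_no_hf_all_zero(self):
        frame, _ = prepare_survival(
            [assignment("p1", Subtype.NOHF, ef=60.0)], [registry_row("p1")]
        )
        row = frame.iloc[0]
        assert (row["HFrEF"], row["HFmrEF"], row["HFpEF"]) == (0, 0, 0)

    def test_event_and_indicator_coding(self):
        frame, _ = prepare_survival(
            [assignment("p1", Subtype.HFREF)], [registry_row("p1", died=True)]
        )
        row = frame.iloc[0]
        assert row["event"] == 1 and row["HFrEF"] == 1

    def test_indeterminate_excluded_and_counted(self):
        frame, summary = prepare_survival(
            [assignment("p1", Subtype.INDETERMINATE, ef=60.0)], [registry_row("p1")]
        )
        assert len(frame) == 0
        assert summary["dropped_indeterminate"] == 1

    def test_zero_length_followup_rejected_with_id(self):
        frame, summary = prepare_survival(
            [assignment("p1", Subtype.HFREF)], [registry_row("p1", entry=65.0, exit_=65.0)]
        )
        assert len(frame) == 0
        assert summary["rejected_bad_followup"] == ["p1"]


def _synthetic_records(n, seed, null_hazards=False, balanced=False):
    kwargs = {}
    if balanced:
        # equal subtype arms give every indicator enough events at small n
        kwargs["subtype_mix"] = {
            Subtype.HFREF: 0.25,
            Subtype.HFMREF: 0.25,
            Subtype.HFPEF: 0.25,
            Subtype.NOHF: 0.25,
        }
    if null_hazards:
        kwargs["subtype_log_hr"] = {s: 0.0 for s in Subtype if s is not Subtype.INDETERMINATE}
        kwargs["covariate_log_hr"] = {
            "male": 0.0,
            "egfr": 0.0,
            "hypertension": 0.0,
            "ischemic_heart_disease": 0.0,
            "type2_diabetes": 0.0,
            "copd": 0.0,
            "renal_failure": 0.0,
        }
    config = GenConfig(n_patients=n, seed=seed, **kwargs)
    _, _, registry, truth = generate_corpus(config)
    return cohort_survival_frame(truth, registry), config


class TestFitCox:
    def test_null_covariate_ci_covers_one(self):
        records, _ = _synthetic_records(2000, seed=5, null_hazards=True, balanced=True)
        estimates, _ = fit_cox(records)
        for term in SUBTYPE_TERMS:
            e = estimates[term]
            assert e.ci_low <= 1.0 <= e.ci_high

    def test_recovers_generative_log_hazard_within_three_se(self):
        records, config = _synthetic_records(5000, seed=17)
        estimates, _ = fit_cox(records)
        for term in SUBTYPE_TERMS:
            e = estimates[term]
            se = (math.log(e.ci_high) - math.log(e.hazard_ratio)) / 1.959963984540054
            truth = config.subtype_log_hr[Subtype(term)]
            assert abs(math.log(e.hazard_ratio) - truth) <= 3 * se

    def test_duplicated_data_similar_point_estimate_narrower_ci(self):
        # duplication creates ties, so under the Efron tie correction the
        # point estimate moves slightly; precision must still double
        records, _ = _synthetic_records(1500, seed=23, balanced=True)
        doubled = pd.concat([records, records], ignore_index=True)
        single, _ = fit_cox(records)
        double, _ = fit_cox(doubled)
        for term in SUBTYPE_TERMS:
            assert double[term].hazard_ratio == pytest.approx(
                single[term].hazard_ratio, rel=0.05
            )
            width = lambda e: math.log(e.ci_high) - math.log(e.ci_low)
            assert width(double[term]) < width(single[term])

    def test_no_events_for_term_is_diagnostic_error(self):
        records, _ = _synthetic_records(300, seed=31, balanced=True)
        records = records.copy()
        records.loc[records["copd"] == 1, "event"] = 0
        if records.loc[records["copd"] == 1].empty:  # pragma: no cover
            pytest.skip("no COPD patients drawn")
        with pytest.raises(DomainError, match="copd"):
            fit_cox(records)


class TestSchoenfeld:
    def test_residual_rows_equal_event_count(self):
        records, _ = _synthetic_records(800, seed=3)
        _, cph = fit_cox(records)
        table, pvalues = schoenfeld_check(cph, records)
        assert len(table) == int(records["event"].sum())
        assert set(pvalues) == set(SUBTYPE_TERMS) | set(DEFAULT_COVARIATES)

    def test_absent_term_is_error(self):
        records, _ = _synthetic_records(800, seed=3)
        _, cph = fit_cox(records)
        with pytest.raises(DomainError, match="absent"):
            schoenfeld_check(cph, records, covariates=["male", "bmi"])

    def test_no_events_is_error(self):
        records, _ = _synthetic_records(800, seed=3)
        _, cph = fit_cox(records)
        censored = records.copy()
        censored["event"] = 0
        with pytest.raises(DomainError, match="events"):
            schoenfeld_check(cph, censored)

    def test_raw_residuals_match_lifelines_without_truncation(self):
        """Dual route: on data with no delayed entry our risk-set computation
        must agree with lifelines' Schoenfeld residuals exactly."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        n = 400
        x = rng.binomial(1, 0.4, n).astype(float)
        z = rng.normal(size=n)
        tte = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x + 0.3 * z)))
        cens = rng.uniform(0, 15, n)
        df = pd.DataFrame(
            {
                "entry_age": 0.0,
                "exit_age": np.minimum(tte, cens),
                "event": (tte <= cens).astype(int),
                "x": x,
                "z": z,
            }
        )
        cph = CoxPHFitter().fit(df[["exit_age", "event", "x", "z"]], "exit_age", "event")
        beta = cph.params_.to_numpy()
        ages, scaled = _scaled_schoenfeld(df, ["x", "z"], beta)
        # invert our scaling to raw residuals and compare with lifelines
        entry = df["entry_age"].to_numpy()
        info = np.zeros((2, 2))
        X = df[["x", "z"]].to_numpy()
        w = np.exp(X @ beta)
        for t in ages:
            m = (entry < t) & (df["exit_age"].to_numpy() >= t)
            ww, xr = w[m], X[m]
            xbar = (ww[:, None] * xr).sum(0) / ww.sum()
            c = xr - xbar
            info += (ww[:, None] * c).T @ c / ww.sum()
        raw_mine = (scaled - beta) @ info / len(ages)
        res = cph.compute_residuals(df[["exit_age", "event", "x", "z"]], "schoenfeld")
        res = res.assign(age=df.loc[res.index, "exit_age"]).sort_values("age")
        np.testing.assert_allclose(raw_mine, res[["x", "z"]].to_numpy(), atol=1e-8)

    def test_proportional_data_trend_mostly_null(self):
        """Under proportional hazards the per-term trend p-values are not
        systematically small."""
        records, _ = _synthetic_records(2500, seed=41)
        _, cph = fit_cox(records)
        _, pvalues = schoenfeld_check(cph, records)
        assert sum(p > 0.01 for p in pvalues.values()) >= 8  # of 10 terms
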