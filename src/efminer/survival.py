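"""Cox proportional-hazards analysis of mortality by HF subtype.

Age is the time scale: each patient enters the risk set at their
follow-up entry age (left truncation) and leaves at their exit age by
death or censoring.  Subtypes are coded as three indicators against a
no-HF reference; the default covariate set mirrors common HF risk
factors (sex, eGFR, hypertension, ischemic heart disease, type-2
diabetes, COPD, renal failure).  Fitting is delegated to lifelines'
:class:`~lifelines.CoxPHFitter` (partial likelihood with Efron tie
handling); proportionality is checked with scaled Schoenfeld residuals
against event age plus a per-term linear-trend test.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .types import (
    DomainError,
    HazardEstimate,
    RegistryRecord,
    Subtype,
    SubtypeAssignment,
)

logger = logging.getLogger(__name__)

SUBTYPE_TERMS = ("HFrEF", "HFmrEF", "HFpEF")

DEFAULT_COVARIATES = (
    "male",
    "egfr",
    "hypertension",
    "ischemic_heart_disease",
    "type2_diabetes",
    "copd",
    "renal_failure",
)


def prepare_survival(
    assignments: Sequence[SubtypeAssignment],
    registry: Sequence[RegistryRecord],
) -> tuple[pd.DataFrame, dict]:
    """Merge subtype calls with registry follow-up into a model table.

    Indeterminate patients are dropped (counted), as are records whose
    exit age does not exceed their entry age.  Subtype is encoded as
    three 0/1 indicator columns with no-HF as the reference.
    """
    registry_by_id = {r.patient_id: r for r in registry}
    rows = []
    summary = {
        "input": len(assignments),
        "dropped_indeterminate": 0,
        "dropped_no_registry": 0,
        "rejected_bad_followup": [],
    }
    for a in assignments:
        if a.subtype is Subtype.INDETERMINATE:
            summary["dropped_indeterminate"] += 1
            continue
        reg = registry_by_id.get(a.patient_id)
        if reg is None:
            summary["dropped_no_registry"] += 1
            continue
        if reg.followup_exit_age <= reg.followup_entry_age:
            summary["rejected_bad_followup"].append(a.patient_id)
            logger.info("patient %s rejected: exit age <= entry age", a.patient_id)
            continue
        rows.append(
            {
                "patient_id": a.patient_id,
                "entry_age": reg.followup_entry_age,
                "exit_age": reg.followup_exit_age,
                "event": int(reg.died),
                "HFrEF": int(a.subtype is Subtype.HFREF),
                "HFmrEF": int(a.subtype is Subtype.HFMREF),
                "HFpEF": int(a.subtype is Subtype.HFPEF),
                "male": int(reg.sex.value == "male"),
                "egfr": a.egfr if a.egfr is not None else np.nan,
                "hypertension": int(reg.hypertension),
                "ischemic_heart_disease": int(reg.ischemic_heart_disease),
                "type2_diabetes": int(reg.type2_diabetes),
                "copd": int(reg.copd),
                "renal_failure": int(reg.renal_failure),
            }
        )
    frame = pd.DataFrame(rows)
    summary["n_model"] = len(frame)
    return frame, summary


def fit_cox(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[dict[str, HazardEstimate], CoxPHFitter]:
    """Fit the left-truncated Cox model on the age time scale.

    Returns per-term hazard ratios with 95% Wald CIs on the log scale,
    plus the fitted backend object for residual diagnostics.
    """
    terms = list(SUBTYPE_TERMS) + [c for c in covariates if c not in SUBTYPE_TERMS]
    missing = [t for t in terms if t not in records.columns]
    if missing:
        raise DomainError(f"missing model columns: {missing}")
    n_events = int(records["event"].sum())
    if n_events < 1:
        raise DomainError("no events in the data")
    for term in terms:
        col = records[term]
        if col.nunique() > 1 and int(records.loc[col != col.min(), "event"].sum()) == 0:
            raise DomainError(f"no events for modelled term {term!r}")

    df = records[["entry_age", "exit_age", "event"] + terms]
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col="exit_age",
            event_col="event",
            entry_col="entry_age",
        )
    except ConvergenceError as exc:
        raise DomainError(f"Cox fit failed to converge: {exc}") from exc

    estimates: dict[str, HazardEstimate] = {}
    z = stats.norm.ppf(0.975)
    for term in terms:
        beta = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        if not math.isfinite(beta) or not math.isfinite(se):
            raise DomainError(f"non-finite estimate for term {term!r} (separation?)")
        estimates[term] = HazardEstimate(
            term=term,
            hazard_ratio=math.exp(beta),
            ci_low=math.exp(beta - z * se),
            ci_high=math.exp(beta + z * se),
            n_events=n_events,
        )
    return estimates, cph


def _scaled_schoenfeld(
    df: pd.DataFrame, terms: Sequence[str], beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled Schoenfeld residuals for a left-truncated Cox model.

    At each event age *t* the residual is the event subject's covariate
    vector minus the risk-weighted covariate mean over the risk set
    {j : entry_j < t <= exit_j}; scaling follows Grambsch & Therneau:
    ``d * I^{-1} r + beta`` with *I* the accumulated information matrix
    and *d* the number of events.  Returns (event ages, residual matrix).
    """
    entry = df["entry_age"].to_numpy(dtype=float)
    exit_ = df["exit_age"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    x = df[list(terms)].to_numpy(dtype=float)
    weights = np.exp(x @ beta)

    event_ages = exit_[event]
    order = np.argsort(event_ages, kind="stable")
    event_ages = event_ages[order]
    event_x = x[event][order]

    p = x.shape[1]
    raw = np.empty((len(event_ages), p))
    info = np.zeros((p, p))
    for k, t in enumerate(event_ages):
        at_risk = (entry < t) & (exit_ >= t)
        w = weights[at_risk]
        xr = x[at_risk]
        total = w.sum()
        xbar = (w[:, None] * xr).sum(axis=0) / total
        raw[k] = event_x[k] - xbar
        centered = xr - xbar
        info += (w[:, None] * centered).T @ centered / total
    d = len(event_ages)
    scaled = d * raw @ np.linalg.pinv(info) + beta
    return event_ages, scaled


def schoenfeld_check(
    cph: CoxPHFitter,
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scaled Schoenfeld residuals vs event age, with a trend test.

    Returns one row per event (columns: ``event_age`` plus one residual
    series per term — directly plottable) and the two-sided p-value of
    a least-squares linear trend of each residual series on event age.
    Under proportional hazards the slopes are null.
    """
    if int(records["event"].sum()) == 0:
        raise DomainError("no events: Schoenfeld residuals undefined")
    terms = list(SUBTYPE_TERMS) + [c for c in covariates if c not in SUBTYPE_TERMS]
    model_terms = list(cph.params_.index)
    absent = [t for t in terms if t not in model_terms]
    if absent:
        raise DomainError(f"terms absent from fitted model: {absent}")

    df = records[["entry_age", "exit_age", "event"] + model_terms]
    beta = cph.params_.to_numpy(dtype=float)
    event_ages, scaled = _scaled_schoenfeld(df, model_terms, beta)
    table = pd.DataFrame({"event_age": event_ages})
    pvalues: dict[str, float] = {}
    for j, term in enumerate(model_terms):
        table[term] = scaled[:, j]
    for term in terms:
        fit = stats.linregress(event_ages, table[term].to_numpy())
        pvalues[term] = float(fit.pvalue)
    return table, pvalues
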