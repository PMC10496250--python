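"""Heart-failure subtype assignment from EF and NT-proBNP.

The four clinical classes follow the 2016 ESC guideline bands:

* HFrEF  — EF < 40%;
* HFmrEF — EF in [40, 50);
* HFpEF  — EF >= 50% with elevated NT-proBNP (> 125 ng/l);
* no HF  — EF >= 50% with normal NT-proBNP (<= 125 ng/l).

NT-proBNP is only consulted for preserved EF; a preserved-EF patient
with no usable NT-proBNP sample is labelled Indeterminate rather than
silently called no-HF.  A value of exactly 125 ng/l counts as normal
(elevation is strictly greater than the threshold).

The module also computes eGFR (CKD-EPI 2009 creatinine equation,
without the race coefficient) for use as a survival-model covariate.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Optional, Sequence

from .aggregate import EF_LOWER_BOUND, EF_UPPER_BOUND, select_index_ef
from .types import (
    Analyte,
    DomainError,
    EFMeasurement,
    LabResult,
    RegistryRecord,
    Sex,
    Subtype,
    SubtypeAssignment,
)

logger = logging.getLogger(__name__)

PROBNP_THRESHOLD_NG_L = 125.0
UMOL_PER_MGDL = 88.42


def assign_subtype(
    ef: float,
    probnp: Optional[float] = None,
    probnp_threshold: float = PROBNP_THRESHOLD_NG_L,
) -> Subtype:
    """Classify one patient from index EF (%) and NT-proBNP (ng/l)."""
    if not (EF_LOWER_BOUND <= ef <= EF_UPPER_BOUND):
        raise DomainError(f"EF {ef} outside [{EF_LOWER_BOUND}, {EF_UPPER_BOUND}]")
    if ef < 40.0:
        return Subtype.HFREF
    if ef < 50.0:
        return Subtype.HFMREF
    if probnp is None:
        return Subtype.INDETERMINATE
    return Subtype.HFPEF if probnp > probnp_threshold else Subtype.NOHF


def pair_probnp(
    labs: Sequence[LabResult],
    index_date: _dt.date,
    window_days: int = 365,
) -> tuple[Optional[float], Optional[_dt.date]]:
    """Choose the NT-proBNP sample closest to the index EF date.

    Only samples within ±``window_days`` qualify; ties break toward the
    earlier sample.  Returns ``(None, None)`` when no sample qualifies.
    """
    if window_days < 0:
        raise DomainError("window_days must be >= 0")
    candidates = [
        lab
        for lab in labs
        if lab.analyte is Analyte.PROBNP
        and abs((lab.sample_date - index_date).days) <= window_days
    ]
    if not candidates:
        return None, None
    best = min(
        candidates, key=lambda lab: (abs((lab.sample_date - index_date).days), lab.sample_date)
    )
    return best.value, best.sample_date


def nearest_creatinine(
    labs: Sequence[LabResult], index_date: _dt.date
) -> Optional[float]:
    """Creatinine sample nearest to the index date (no window; ties earlier)."""
    candidates = [lab for lab in labs if lab.analyte is Analyte.CREATININE]
    if not candidates:
        return None
    best = min(
        candidates, key=lambda lab: (abs((lab.sample_date - index_date).days), lab.sample_date)
    )
    return best.value


def compute_egfr(creatinine_umol_l: float, age_years: float, sex: Sex) -> float:
    """CKD-EPI 2009 creatinine eGFR in ml/min/1.73 m² (no race term).

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
           · 1.018 [if female]

    with Scr in mg/dl, κ = 0.7 (F) / 0.9 (M), α = −0.329 (F) / −0.411 (M).
    """
    if creatinine_umol_l <= 0:
        raise DomainError("creatinine must be positive")
    if age_years <= 0:
        raise DomainError("age must be positive")
    scr = creatinine_umol_l / UMOL_PER_MGDL
    if sex is Sex.FEMALE:
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    ratio = scr / kappa
    return (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
        * sex_factor
    )


def build_cohort(
    measurements: Sequence[EFMeasurement],
    labs: Sequence[LabResult],
    registry: Sequence[RegistryRecord],
    index_policy: str = "latest",
    reference_date: Optional[_dt.date] = None,
    probnp_window_days: int = 365,
    probnp_threshold: float = PROBNP_THRESHOLD_NG_L,
    require_creatinine: bool = True,
) -> tuple[list[SubtypeAssignment], dict]:
    """Assemble the analysis cohort: index EF + paired labs + subtype.

    Patients with no surviving EF measurement are absent from the
    output; patients with no creatinine are excluded when
    ``require_creatinine`` (the default, needed for the eGFR covariate).
    Returns the assignments plus an exclusion/attrition summary.
    """
    by_patient_meas: dict[str, list[EFMeasurement]] = {}
    for m in measurements:
        by_patient_meas.setdefault(m.patient_id, []).append(m)
    by_patient_labs: dict[str, list[LabResult]] = {}
    for lab in labs:
        by_patient_labs.setdefault(lab.patient_id, []).append(lab)
    registry_by_id = {r.patient_id: r for r in registry}

    out: list[SubtypeAssignment] = []
    summary = {
        "patients_with_ef": len(by_patient_meas),
        "excluded_missing_registry": 0,
        "excluded_missing_creatinine": 0,
        "indeterminate": 0,
        "cohort_size": 0,
    }
    for pid in sorted(by_patient_meas):
        index = select_index_ef(by_patient_meas[pid], index_policy, reference_date)
        assert index is not None
        reg = registry_by_id.get(pid)
        if reg is None:
            summary["excluded_missing_registry"] += 1
            logger.info("patient %s excluded: no registry record", pid)
            continue
        patient_labs = by_patient_labs.get(pid, [])
        creat = nearest_creatinine(patient_labs, index.measure_date)
        if creat is None and require_creatinine:
            summary["excluded_missing_creatinine"] += 1
            logger.info("patient %s excluded: no creatinine", pid)
            continue
        egfr = (
            None
            if creat is None
            else compute_egfr(creat, reg.baseline_age, reg.sex)
        )
        probnp, probnp_date = pair_probnp(
            patient_labs, index.measure_date, probnp_window_days
        )
        subtype = assign_subtype(index.ef_percent, probnp, probnp_threshold)
        if subtype is Subtype.INDETERMINATE:
            summary["indeterminate"] += 1
        out.append(
            SubtypeAssignment(
                patient_id=pid,
                subtype=subtype,
                ef_percent=index.ef_percent,
                ef_date=index.measure_date,
                probnp=probnp,
                probnp_date=probnp_date,
                egfr=egfr,
            )
        )
    summary["cohort_size"] = len(out)
    return out, summary
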