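"""Shared domain types for the EF-mining pipeline.

The pipeline moves patient data through a fixed chain of shapes:
free-text notes (:class:`ClinicalNote`) yield candidate EF readings
(:class:`EFMention`), which are consolidated into per-day measurements
(:class:`EFMeasurement`), combined with laboratory data
(:class:`LabResult`) into heart-failure subtype calls
(:class:`SubtypeAssignment`), and finally joined with registry
follow-up (:class:`RegistryRecord`) for survival analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class SchemaError(ValueError):
    """Raised when an input record violates the documented file schema."""


class DomainError(ValueError):
    """Raised when a value is outside the domain an operation requires."""


class Analyte(str, Enum):
    PROBNP = "probnp"
    CREATININE = "creatinine"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class SourceKind(str, Enum):
    NUMERIC = "numeric"
    RANGE = "range"
    WORDED = "worded"


class MentionStatus(str, Enum):
    ACCEPTED = "accepted"
    REJECTED = "rejected"


class RejectReason(str, Enum):
    DATE_MASQUERADE = "date_masquerade"
    PAST_READING = "past_reading"
    # Defined for completeness of the audit vocabulary; token-level bounds
    # are deliberately not enforced during mining (outlier removal happens
    # after same-day averaging), so this code is never emitted by default.
    OUT_OF_BOUNDS_TOKEN = "out_of_bounds_token"
    NONE = "none"


class Subtype(str, Enum):
    HFREF = "HFrEF"
    HFMREF = "HFmrEF"
    HFPEF = "HFpEF"
    NOHF = "NoHF"
    INDETERMINATE = "Indeterminate"


#: The four mutually exclusive classes used for validation; Indeterminate
#: patients are excluded from confusion matrices.
CONFUSION_LABELS = (Subtype.HFREF, Subtype.HFMREF, Subtype.HFPEF, Subtype.NOHF)


def parse_date(value, *, context: str = "date") -> _dt.date:
    """Parse an ISO-8601 calendar date, raising :class:`SchemaError` otherwise."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise SchemaError(f"unparseable {context}: {value!r}") from exc


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical document for one patient."""

    patient_id: str
    note_id: str
    note_date: _dt.date
    text: str

    def __post_init__(self):
        if not self.patient_id:
            raise SchemaError("patient_id must be non-empty")
        if not self.note_id:
            raise SchemaError("note_id must be non-empty")


@dataclass(frozen=True)
class LabResult:
    """One structured laboratory measurement in canonical units.

    Canonical units: NT-proBNP in ng/l, creatinine in µmol/l.
    """

    patient_id: str
    sample_date: _dt.date
    analyte: Analyte
    value: float
    unit: str

    def __post_init__(self):
        if self.value < 0:
            raise SchemaError(f"lab value must be non-negative, got {self.value}")


@dataclass(frozen=True)
class RegistryRecord:
    """Registry row: demographics, comorbidity flags and survival follow-up."""

    patient_id: str
    sex: Sex
    baseline_age: float
    hypertension: bool
    ischemic_heart_disease: bool
    type2_diabetes: bool
    copd: bool
    renal_failure: bool
    followup_entry_age: float
    followup_exit_age: float
    died: bool

    def __post_init__(self):
        if self.followup_exit_age < self.followup_entry_age:
            raise SchemaError(
                f"exit age {self.followup_exit_age} precedes entry age "
                f"{self.followup_entry_age} for patient {self.patient_id}"
            )


@dataclass(frozen=True)
class EFMention:
    """A single candidate EF reading found in one sentence.

    ``span`` is the 0-based half-open character interval of the matched
    value inside ``sentence``.  Rejected candidates are retained with a
    reason code so the mining run is fully auditable.
    """

    patient_id: str
    note_id: str
    note_date: _dt.date
    sentence: str
    span: tuple[int, int]
    source_kind: SourceKind
    raw_value_low: float
    raw_value_high: float
    resolved_value: float
    status: MentionStatus
    reject_reason: RejectReason

    def __post_init__(self):
        lo, hi = self.span
        if not (0 <= lo <= hi <= len(self.sentence)):
            raise DomainError(f"span {self.span} outside sentence bounds")
        mid = (self.raw_value_low + self.raw_value_high) / 2.0
        if abs(self.resolved_value - mid) > 1e-9:
            raise DomainError("resolved_value must equal the midpoint of raw bounds")
        rejected = self.status is MentionStatus.REJECTED
        has_reason = self.reject_reason is not RejectReason.NONE
        if rejected != has_reason:
            raise DomainError("status=rejected iff reject_reason != none")


@dataclass(frozen=True)
class EFMeasurement:
    """Per-patient, per-date consolidated EF (mean of same-date mentions)."""

    patient_id: str
    measure_date: _dt.date
    ef_percent: float
    n_mentions: int

    def __post_init__(self):
        if self.n_mentions < 1:
            raise DomainError("n_mentions must be >= 1")


@dataclass(frozen=True)
class SubtypeAssignment:
    """Patient-level HF subtype call with the evidence used."""

    patient_id: str
    subtype: Subtype
    ef_percent: float
    ef_date: _dt.date
    probnp: Optional[float] = None
    probnp_date: Optional[_dt.date] = None
    egfr: Optional[float] = None


@dataclass
class ConfusionMatrix:
    """4x4 algorithm-vs-gold counts; rows = algorithm, columns = gold."""

    labels: tuple = CONFUSION_LABELS
    counts: list = field(default_factory=lambda: [[0] * 4 for _ in range(4)])

    @property
    def n(self) -> int:
        return int(sum(sum(row) for row in self.counts))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest diagnostic metrics for a class (percent scale).

    Undefined ratios (0/0) are reported as ``None``, never as 0.
    """

    label: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]


@dataclass(frozen=True)
class HazardEstimate:
    """A fitted hazard ratio with its 95% confidence interval."""

    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    n_events: int

    def __post_init__(self):
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise DomainError(f"CI does not bracket HR for term {self.term}")
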