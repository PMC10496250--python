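"""Readers and writers for all pipeline artifacts.

File conventions: notes are JSONL (one object per line) or CSV with
columns ``patient_id,note_id,note_date,text``; labs are CSV
``patient_id,sample_date,analyte,value,unit``; the registry is CSV with
demographics, comorbidity flags and follow-up ages; the mention audit
trail round-trips losslessly through :func:`write_audit` /
:func:`read_audit`.  All CSVs are comma-separated UTF-8 with a header
row; dates are ISO-8601.
"""

from __future__ import annotations

import csv
import json
import warnings
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    Analyte,
    ClinicalNote,
    EFMeasurement,
    EFMention,
    LabResult,
    MentionStatus,
    RegistryRecord,
    RejectReason,
    SchemaError,
    Sex,
    SourceKind,
    SubtypeAssignment,
    Subtype,
    parse_date,
)

NOTE_FIELDS = ("patient_id", "note_id", "note_date", "text")

#: Fixed audit-trail column order (documented in the README).
AUDIT_COLUMNS = (
    "patient_id",
    "note_id",
    "note_date",
    "sentence",
    "span_start",
    "span_end",
    "source_kind",
    "raw_value_low",
    "raw_value_high",
    "resolved_value",
    "status",
    "reject_reason",
)

#: Canonical units per analyte.
CANONICAL_UNITS = {Analyte.PROBNP: "ng/l", Analyte.CREATININE: "µmol/l"}

#: Multiplicative conversions to canonical units, keyed (analyte, unit).
#: NT-proBNP: 1 pg/ml == 1 ng/l.  Creatinine: 1 mg/dl == 88.42 µmol/l.
DEFAULT_UNIT_MAP = {
    (Analyte.PROBNP, "ng/l"): 1.0,
    (Analyte.PROBNP, "pg/ml"): 1.0,
    (Analyte.CREATININE, "µmol/l"): 1.0,
    (Analyte.CREATININE, "umol/l"): 1.0,
    (Analyte.CREATININE, "mg/dl"): 88.42,
}

DEFAULT_ANALYTE_MAP = {
    "probnp": Analyte.PROBNP,
    "nt-probnp": Analyte.PROBNP,
    "ntprobnp": Analyte.PROBNP,
    "creatinine": Analyte.CREATININE,
    "krea": Analyte.CREATININE,
}


def _note_from_record(rec: dict, index: int) -> ClinicalNote:
    for name in NOTE_FIELDS:
        if name not in rec or rec[name] is None:
            raise SchemaError(f"record {index}: missing field {name!r}")
    return ClinicalNote(
        patient_id=str(rec["patient_id"]),
        note_id=str(rec["note_id"]),
        note_date=parse_date(rec["note_date"], context=f"note_date in record {index}"),
        text=str(rec["text"]),
    )


def read_notes(path, format: str = "jsonl") -> list[ClinicalNote]:
    """Read clinical notes in file order from a JSONL or CSV file."""
    notes: list[ClinicalNote] = []
    if format == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {lineno}: invalid JSON: {exc}") from exc
                notes.append(_note_from_record(rec, lineno))
    elif format == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = set(NOTE_FIELDS) - set(reader.fieldnames)
            if missing:
                raise SchemaError(f"notes CSV missing columns: {sorted(missing)}")
            for index, rec in enumerate(reader, start=1):
                notes.append(_note_from_record(rec, index))
    else:
        raise SchemaError(f"unknown notes format: {format!r}")
    return notes


def write_notes(notes: Iterable[ClinicalNote], path, format: str = "jsonl") -> None:
    notes = list(notes)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for n in notes:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": n.patient_id,
                            "note_id": n.note_id,
                            "note_date": n.note_date.isoformat(),
                            "text": n.text,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(NOTE_FIELDS)
            for n in notes:
                writer.writerow(
                    [n.patient_id, n.note_id, n.note_date.isoformat(), n.text]
                )
    else:
        raise SchemaError(f"unknown notes format: {format!r}")


def read_labs(
    path,
    unit_map: Optional[dict] = None,
    analyte_map: Optional[dict] = None,
) -> list[LabResult]:
    """Read laboratory results, converting values to canonical units.

    Unknown analytes are skipped with a single summary warning; unknown
    units raise :class:`SchemaError`.
    """
    conversions = dict(DEFAULT_UNIT_MAP)
    if unit_map:
        for (analyte, unit), factor in unit_map.items():
            conversions[(Analyte(analyte), unit)] = float(factor)
    names = dict(DEFAULT_ANALYTE_MAP)
    if analyte_map:
        names.update({k.lower(): Analyte(v) for k, v in analyte_map.items()})

    results: list[LabResult] = []
    skipped = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "sample_date", "analyte", "value", "unit"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise SchemaError("labs CSV must have columns " + ",".join(sorted(required)))
        for index, rec in enumerate(reader, start=1):
            analyte = names.get(str(rec["analyte"]).strip().lower())
            if analyte is None:
                skipped += 1
                continue
            unit = str(rec["unit"]).strip()
            factor = conversions.get((analyte, unit))
            if factor is None:
                raise SchemaError(
                    f"record {index}: unknown unit {unit!r} for analyte {analyte.value}"
                )
            results.append(
                LabResult(
                    patient_id=str(rec["patient_id"]),
                    sample_date=parse_date(
                        rec["sample_date"], context=f"sample_date in record {index}"
                    ),
                    analyte=analyte,
                    value=float(rec["value"]) * factor,
                    unit=CANONICAL_UNITS[analyte],
                )
            )
    if skipped:
        warnings.warn(f"read_labs: skipped {skipped} record(s) with unknown analyte")
    return results


REGISTRY_COLUMNS = (
    "patient_id",
    "sex",
    "baseline_age",
    "hypertension",
    "ischemic_heart_disease",
    "type2_diabetes",
    "copd",
    "renal_failure",
    "followup_entry_age",
    "followup_exit_age",
    "died",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(value, field: str, index: int) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise SchemaError(f"record {index}: non-boolean value {value!r} for {field}")


def read_registry(path) -> list[RegistryRecord]:
    records: list[RegistryRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(REGISTRY_COLUMNS) - set(reader.fieldnames):
            raise SchemaError(
                "registry CSV must have columns " + ",".join(REGISTRY_COLUMNS)
            )
        for index, rec in enumerate(reader, start=1):
            flags = {
                f: _parse_bool(rec[f], f, index)
                for f in (
                    "hypertension",
                    "ischemic_heart_disease",
                    "type2_diabetes",
                    "copd",
                    "renal_failure",
                    "died",
                )
            }
            records.append(
                RegistryRecord(
                    patient_id=str(rec["patient_id"]),
                    sex=Sex(str(rec["sex"]).strip().lower()),
                    baseline_age=float(rec["baseline_age"]),
                    hypertension=flags["hypertension"],
                    ischemic_heart_disease=flags["ischemic_heart_disease"],
                    type2_diabetes=flags["type2_diabetes"],
                    copd=flags["copd"],
                    renal_failure=flags["renal_failure"],
                    followup_entry_age=float(rec["followup_entry_age"]),
                    followup_exit_age=float(rec["followup_exit_age"]),
                    died=flags["died"],
                )
            )
    return records


def write_registry(records: Iterable[RegistryRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.sex.value,
                    r.baseline_age,
                    int(r.hypertension),
                    int(r.ischemic_heart_disease),
                    int(r.type2_diabetes),
                    int(r.copd),
                    int(r.renal_failure),
                    r.followup_entry_age,
                    r.followup_exit_age,
                    int(r.died),
                ]
            )


def write_labs(labs: Iterable[LabResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "sample_date", "analyte", "value", "unit"])
        for lab in labs:
            writer.writerow(
                [
                    lab.patient_id,
                    lab.sample_date.isoformat(),
                    lab.analyte.value,
                    repr(lab.value),
                    lab.unit,
                ]
            )


def write_audit(mentions: Sequence[EFMention], path) -> None:
    """Write the mention audit trail (one row per candidate, accepted or not)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(AUDIT_COLUMNS)
        for m in mentions:
            writer.writerow(
                [
                    m.patient_id,
                    m.note_id,
                    m.note_date.isoformat(),
                    m.sentence,
                    m.span[0],
                    m.span[1],
                    m.source_kind.value,
                    repr(m.raw_value_low),
                    repr(m.raw_value_high),
                    repr(m.resolved_value),
                    m.status.value,
                    m.reject_reason.value,
                ]
            )


def read_audit(path) -> list[EFMention]:
    """Read an audit trail written by :func:`write_audit` (lossless round-trip)."""
    mentions: list[EFMention] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(AUDIT_COLUMNS) - set(reader.fieldnames):
            raise SchemaError("audit CSV must have columns " + ",".join(AUDIT_COLUMNS))
        for rec in reader:
            mentions.append(
                EFMention(
                    patient_id=rec["patient_id"],
                    note_id=rec["note_id"],
                    note_date=parse_date(rec["note_date"]),
                    sentence=rec["sentence"],
                    span=(int(rec["span_start"]), int(rec["span_end"])),
                    source_kind=SourceKind(rec["source_kind"]),
                    raw_value_low=float(rec["raw_value_low"]),
                    raw_value_high=float(rec["raw_value_high"]),
                    resolved_value=float(rec["resolved_value"]),
                    status=MentionStatus(rec["status"]),
                    reject_reason=RejectReason(rec["reject_reason"]),
                )
            )
    return mentions


def measurements_to_frame(measurements: Sequence[EFMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "measure_date": m.measure_date.isoformat(),
                "ef_percent": m.ef_percent,
                "n_mentions": m.n_mentions,
            }
            for m in measurements
        ],
        columns=["patient_id", "measure_date", "ef_percent", "n_mentions"],
    )


def read_measurements(path) -> list[EFMeasurement]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return [
        EFMeasurement(
            patient_id=row.patient_id,
            measure_date=parse_date(row.measure_date),
            ef_percent=float(row.ef_percent),
            n_mentions=int(row.n_mentions),
        )
        for row in frame.itertuples()
    ]


def subtypes_to_frame(assignments: Sequence[SubtypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "subtype": a.subtype.value,
                "ef_percent": a.ef_percent,
                "ef_date": a.ef_date.isoformat(),
                "probnp": a.probnp,
                "probnp_date": None if a.probnp_date is None else a.probnp_date.isoformat(),
                "egfr": a.egfr,
            }
            for a in assignments
        ],
        columns=[
            "patient_id",
            "subtype",
            "ef_percent",
            "ef_date",
            "probnp",
            "probnp_date",
            "egfr",
        ],
    )


def read_subtypes(path) -> list[SubtypeAssignment]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for row in frame.itertuples():
        probnp = None if pd.isna(row.probnp) else float(row.probnp)
        probnp_date = (
            None if pd.isna(row.probnp_date) else parse_date(row.probnp_date)
        )
        egfr = None if pd.isna(row.egfr) else float(row.egfr)
        out.append(
            SubtypeAssignment(
                patient_id=row.patient_id,
                subtype=Subtype(row.subtype),
                ef_percent=float(row.ef_percent),
                ef_date=parse_date(row.ef_date),
                probnp=probnp,
                probnp_date=probnp_date,
                egfr=egfr,
            )
        )
    return out
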