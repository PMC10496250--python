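"""Consolidation of accepted EF mentions into per-patient, per-date values.

Several readings observed on the same calendar day are averaged; the
daily mean is then subject to outlier removal (values below 10% or
above 90% are physiologically implausible as true EF and are dropped,
bounds inclusive on the keep side).  One measurement per patient is
finally selected as the index EF that defines their current state.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import defaultdict
from typing import Optional, Sequence

from .types import DomainError, EFMeasurement, EFMention, MentionStatus

logger = logging.getLogger(__name__)

EF_LOWER_BOUND = 10.0
EF_UPPER_BOUND = 90.0


def daily_mean(mentions: Sequence[EFMention]) -> list[EFMeasurement]:
    """Average accepted mentions per (patient, calendar day).

    Ordered by patient id then date.  Raises if any mention is not
    accepted (rejected candidates must be filtered upstream).
    """
    groups: dict[tuple[str, _dt.date], list[float]] = defaultdict(list)
    for m in mentions:
        if m.status is not MentionStatus.ACCEPTED:
            raise DomainError("daily_mean requires accepted mentions only")
        groups[(m.patient_id, m.note_date)].append(m.resolved_value)
    # summing in sorted order makes the mean exactly permutation-invariant
    return [
        EFMeasurement(
            patient_id=pid,
            measure_date=date,
            ef_percent=sum(sorted(values)) / len(values),
            n_mentions=len(values),
        )
        for (pid, date), values in sorted(groups.items())
    ]


def filter_outliers(measurements: Sequence[EFMeasurement]) -> list[EFMeasurement]:
    """Drop daily means outside [10, 90] percent (strictly <10 or >90 removed)."""
    kept = []
    for m in measurements:
        if EF_LOWER_BOUND <= m.ef_percent <= EF_UPPER_BOUND:
            kept.append(m)
        else:
            logger.info(
                "outlier removed: patient=%s date=%s ef=%.1f",
                m.patient_id,
                m.measure_date,
                m.ef_percent,
            )
    return kept


def select_index_ef(
    measurements: Sequence[EFMeasurement],
    policy: str = "latest",
    reference_date: Optional[_dt.date] = None,
) -> Optional[EFMeasurement]:
    """Pick the single measurement that represents one patient's state.

    Policies: ``latest`` (default — most recent EF defines the current
    subtype), ``earliest``, or ``nearest_to`` a reference date (ties
    broken toward the earlier date).  Returns ``None`` for a patient
    with no surviving measurement.
    """
    ms = list(measurements)
    if not ms:
        return None
    pids = {m.patient_id for m in ms}
    if len(pids) > 1:
        raise DomainError(f"select_index_ef expects one patient, got {sorted(pids)}")
    if policy == "latest":
        return max(ms, key=lambda m: m.measure_date)
    if policy == "earliest":
        return min(ms, key=lambda m: m.measure_date)
    if policy == "nearest_to":
        if reference_date is None:
            raise DomainError("policy 'nearest_to' requires a reference_date")
        return min(
            ms, key=lambda m: (abs((m.measure_date - reference_date).days), m.measure_date)
        )
    raise DomainError(f"unknown index policy: {policy!r}")


def aggregate_mentions(mentions: Sequence[EFMention]) -> list[EFMeasurement]:
    """Full consolidation: keep accepted mentions, average per day, filter."""
    accepted = [m for m in mentions if m.status is MentionStatus.ACCEPTED]
    return filter_outliers(daily_mean(accepted))
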