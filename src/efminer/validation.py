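"""Validation of algorithm output against a clinician gold standard.

Builds the 4-class (HFrEF / HFmrEF / HFpEF / no-HF) confusion matrix
with algorithm labels as rows and gold labels as columns, derives
one-vs-rest diagnostic metrics per class and for "HF of any subtype",
and summarises EF-value agreement (exact, within a tolerance in EF
percentage points, and same guideline band).

Metrics are kept at full precision internally; display rounding is
half-up to integer percents.  Ratios with zero denominator are
reported as missing, never as zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional

from .types import (
    CONFUSION_LABELS,
    ClassMetrics,
    ConfusionMatrix,
    DomainError,
    Subtype,
)

HF_ANY = "HF-any"

EF_BAND_EDGES = (40.0, 50.0)


def build_confusion(
    pred: Mapping[str, Subtype], gold: Mapping[str, Subtype]
) -> ConfusionMatrix:
    """Cross-tabulate algorithm vs gold labels over the same patient set."""
    only_pred = sorted(set(pred) - set(gold))
    only_gold = sorted(set(gold) - set(pred))
    if only_pred or only_gold:
        raise DomainError(
            f"patient sets differ: only in pred {only_pred}, only in gold {only_gold}"
        )
    index = {label: i for i, label in enumerate(CONFUSION_LABELS)}
    cm = ConfusionMatrix()
    for pid in pred:
        p, g = pred[pid], gold[pid]
        if p not in index or g not in index:
            raise DomainError(f"patient {pid}: label outside the 4-class set ({p}, {g})")
        cm.counts[index[p]][index[g]] += 1
    return cm


def _collapse(cm: ConfusionMatrix, target) -> tuple[int, int, int, int]:
    """One-vs-rest collapse to (TP, FP, FN, TN)."""
    if target == HF_ANY:
        positive = {Subtype.HFREF, Subtype.HFMREF, Subtype.HFPEF}
    else:
        positive = {Subtype(target)}
    tp = fp = fn = tn = 0
    for i, row_label in enumerate(cm.labels):
        for j, col_label in enumerate(cm.labels):
            c = cm.counts[i][j]
            if row_label in positive and col_label in positive:
                tp += c
            elif row_label in positive:
                fp += c
            elif col_label in positive:
                fn += c
            else:
                tn += c
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def class_metrics(cm: ConfusionMatrix, target) -> ClassMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy (percent) for a class.

    ``target`` is one of the four subtype labels or ``"HF-any"``
    (positive = any HF subtype).
    """
    if cm.n == 0:
        raise DomainError("confusion matrix is empty")
    tp, fp, fn, tn = _collapse(cm, target)
    label = target if target == HF_ANY else Subtype(target).value
    return ClassMetrics(
        label=label,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, cm.n),
    )


def round_percent(value: Optional[float]) -> Optional[int]:
    """Display rounding: half-up to integer percent."""
    if value is None:
        return None
    return int(math.floor(value + 0.5))


def ef_band(ef: float) -> str:
    lo, hi = EF_BAND_EDGES
    if ef < lo:
        return "<40"
    if ef < hi:
        return "40-49"
    return ">=50"


def ef_agreement(
    algo_ef: Mapping[str, float],
    gold_ef: Mapping[str, float],
    tolerance: float = 5.0,
) -> dict:
    """EF-value agreement between algorithm and gold standard.

    Reports the proportion of patients with exactly equal EF, with an
    absolute difference within ``tolerance`` EF percentage points, and
    within the same guideline band (<40, 40-49, >=50).
    """
    if set(algo_ef) != set(gold_ef):
        raise DomainError("algo and gold EF tables must cover the same patients")
    if not algo_ef:
        raise DomainError("empty pairing")
    n = len(algo_ef)
    exact = within = same_band = 0
    for pid, a in algo_ef.items():
        g = gold_ef[pid]
        if a == g:
            exact += 1
        if abs(a - g) <= tolerance:
            within += 1
        if ef_band(a) == ef_band(g):
            same_band += 1
    return {
        "n": n,
        "exact_pct": 100.0 * exact / n,
        "within_tolerance_pct": 100.0 * within / n,
        "same_band_pct": 100.0 * same_band / n,
        "tolerance": tolerance,
    }


def metrics_report(
    pred: Mapping[str, Subtype], gold: Mapping[str, Subtype]
) -> dict:
    """Confusion matrix plus per-class and HF-any metrics as a JSON-able dict.

    Indeterminate predictions are excluded (with a count) before the
    matrix is built: validation covers only patients the algorithm
    could classify into the four classes.
    """
    determinate = {
        pid: lab for pid, lab in pred.items() if lab is not Subtype.INDETERMINATE
    }
    n_excluded = len(pred) - len(determinate)
    gold_subset = {pid: gold[pid] for pid in determinate}
    cm = build_confusion(determinate, gold_subset)
    targets = [s.value for s in CONFUSION_LABELS] + [HF_ANY]
    per_class = {}
    for target in targets:
        m = class_metrics(cm, target)
        per_class[m.label] = {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
            "npv": m.npv,
            "accuracy": m.accuracy,
            "display": {
                k: round_percent(v)
                for k, v in [
                    ("sensitivity", m.sensitivity),
                    ("specificity", m.specificity),
                    ("ppv", m.ppv),
                    ("npv", m.npv),
                    ("accuracy", m.accuracy),
                ]
            },
        }
    return {
        "labels": [s.value for s in cm.labels],
        "counts": cm.counts,
        "n": cm.n,
        "excluded_indeterminate": n_excluded,
        "metrics": per_class,
    }
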