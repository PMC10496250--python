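# efminer

Rule-based mining of left-ventricular **ejection fraction (EF)** values from
unstructured clinical text, and **heart-failure (HF) subtyping** from the mined
EF combined with structured NT-proBNP laboratory data.

Registers and ICD coding typically carry a single congestive-HF code, so
epidemiological studies cannot separate HF with reduced, mildly reduced and
preserved ejection fraction. This package implements a computable phenotype
that recovers the missing EF from free-text echo and clinical reports, assigns
the guideline subtype, quantifies how well the assignment agrees with
clinician chart review, and supports downstream mortality analysis. It is
aimed at biobank/EHR researchers who need HF subtypes at scale without manual
review, and ships a synthetic-EHR generator so the whole pipeline is testable
without access-restricted hospital data.

## The algorithm

For each note, sentences containing a trigger term (`EF`, case-sensitive at a
word boundary, or `ejection fraction`, case-insensitive) are scanned in a
fixed cascade:

1. **ranges** — two two-digit numbers joined by a hyphen with a percent
   marker (`EF 35-40%`), collapsed to the interval midpoint;
2. **numeric values** — a two-digit integer part, optional `.`/`,` decimal,
   followed by `%` or the word `percent` (`EF 35%`, `EF was 55 percent`);
3. **worded descriptions**, only if no numeric/range candidate survived —
   mapped to the 2016 ESC guideline anchors
   `preserved → 50`, `mildly reduced → 45`, `reduced → 39`
   (plus configurable extras, e.g. `severely reduced → 25`, `normal → 60`).

Quality checks reject candidates that are date fragments masquerading as
readings (`12.5.2019`) and whole sentences reporting past measurements
(`EF 40% a year ago`, `in 2018`). Accepted readings on the same calendar day
are averaged; daily means outside **[10, 90]%** are discarded as outliers; one
index EF per patient (latest, by default) then defines the subtype together
with the NT-proBNP sample nearest in time (±365 d):

| EF | NT-proBNP | subtype |
|---|---|---|
| < 40% | (ignored) | HFrEF |
| 40–49% | (ignored) | HFmrEF |
| ≥ 50% | > 125 ng/l | HFpEF |
| ≥ 50% | ≤ 125 ng/l | no HF |
| ≥ 50% | missing | indeterminate |

Validation reproduces the standard one-vs-rest diagnostic metrics
(sensitivity, specificity, PPV, NPV, accuracy) from the 4×4
algorithm-vs-clinician confusion matrix, and the survival module fits Cox
proportional-hazards models of all-cause mortality with **age as the time
scale** (left truncation at entry age), subtype indicators against a no-HF
reference, covariates (sex, CKD-EPI eGFR, five comorbidity flags), and a
scaled-Schoenfeld proportionality check.

## Worked example

```python
import datetime as dt
from efminer import ClinicalNote, extract_mentions, aggregate_mentions, default_lexicon

note = ClinicalNote(
    patient_id="p42", note_id="n1", note_date=dt.date(2019, 3, 2),
    text="Echo 1.3.2019: EF 35-40%. EF 55% a year ago. Patient stable.",
)
mentions = extract_mentions(note, default_lexicon())
for m in mentions:
    print(f"{m.source_kind.value:8s} {m.resolved_value:5.1f}  {m.status.value:8s} {m.reject_reason.value}")
for meas in aggregate_mentions(mentions):
    print(f"index EF for {meas.patient_id} on {meas.measure_date}: {meas.ef_percent}% (from {meas.n_mentions} mention)")
```

prints

```text
range     37.5  accepted none
numeric   55.0  rejected past_reading
index EF for p42 on 2019-03-02: 37.5% (from 1 mention)
```

The range `35-40%` resolves to its midpoint 37.5; the date `1.3.2019` never
becomes a candidate; the historical `EF 55%` is kept in the audit trail but
rejected as a past reading, so the day's EF is 37.5% — an HFrEF-band value.

The same stages are available from the shell:

```sh
efminer simulate --n-patients 1000 --seed 7 --outdir sim/
efminer mine      --notes sim/notes.jsonl --out sim/mentions.csv --audit sim/audit.csv
efminer aggregate --mentions sim/mentions.csv --out sim/ef.csv
efminer subtype   --ef sim/ef.csv --labs sim/labs.csv --registry sim/registry.csv --out sim/subtypes.csv
efminer survive   --subtypes sim/subtypes.csv --registry sim/registry.csv --out sim/hazards.json
```

or end to end with `efminer run --config pipeline.yaml`, which writes a JSON
run summary with per-stage counts and exclusion tallies. The audit trail CSV
has the fixed column order
`patient_id,note_id,note_date,sentence,span_start,span_end,source_kind,raw_value_low,raw_value_high,resolved_value,status,reject_reason`.

The synthetic generator plants ground-truth EF mentions (numeric, ranges,
worded descriptions, several same-day readings) and distractors (past
readings, bare dates, non-EF percentages), draws subtype-consistent NT-proBNP
and creatinine, and simulates survival under proportional hazards with
subtype hazard ratios 2.63 (HFrEF), 1.91 (HFmrEF) and 2.28 (HFpEF) by
default; `efminer.synth.score_extraction` scores mined mentions against the
planted truth.

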