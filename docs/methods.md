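# Methods

This note records the models and procedures efminer implements, the
parameters that matter, the design choices made where the underlying
description was open, and what the synthetic-data tests do and do not show.

## Text-mining model

The extractor is deliberately rule-based: regular expressions plus string
matching, no statistical NLP. Sentence segmentation treats `.`, `!`, `?` and
newline as terminators, except a period flanked by digits, which keeps
decimal values (`35.5`) and day-first dates (`12.5.2019`) inside one
sentence. Offsets are 0-based and half-open throughout.

Trigger matching distinguishes the abbreviation `EF` (case-sensitive, word
boundaries — lower-casing it would match fragments of ordinary words) from
multi-word triggers (case-insensitive). Candidate values are searched
rightward from the trigger within the sentence; additionally the two tokens
immediately left of the trigger are scanned, so constructions like
`55% EF` are found (`left_tokens=2`, set 0 to disable).

A "two-digit" value means a two-digit integer part with an optional decimal
part after `.` or `,` (decimal comma is common in European notes).
Single-digit percentages are below any plausible EF reporting convention and
three-digit ones are impossible, so neither is ever a candidate — this also
prevents four-digit years from matching. A range (`35-40%`, percent marker on
either or both endpoints) is collapsed to its arithmetic midpoint; the
source never states a collapse rule, and the midpoint is the unbiased choice
for an interval report. A matched range suppresses numeric sub-matches of
its own digits.

The worded fallback fires only in sentences where no numeric or range
candidate was *accepted*: a sentence whose only numbers are date fragments
can still contribute a worded reading. Phrases match longest-first so
`mildly reduced` can never also fire `reduced`. The three anchors
(50/45/39) come from the 2016 ESC guideline bands; the shipped extras
(`severely reduced → 25`, `normal → 60`) are this package's defaults, chosen
on clinical grounds, and live in a YAML lexicon
(`src/efminer/lexicons/en.yaml`) so a localized production vocabulary can be
dropped in without code changes.

Quality checks: (a) a numeric candidate whose digits overlap a date-shaped
token (`dd.mm.yyyy`, `dd/mm/yyyy`, `dd.mm.`, `d.m.yy`, or a two-digit number
immediately followed by a four-digit year) is rejected as `date_masquerade`;
(b) a sentence containing a past-tense qualifier (`a year ago`, `years ago`,
`previously`, …, or the pattern `in <four-digit year>`) has *all* of its
candidates rejected as `past_reading`. The scope of the past-reading rule is
the sentence; cross-sentence temporal reasoning is out of scope. Every
candidate, accepted or rejected, is emitted with a reason code — the audit
trail is first-class because mis-averaged or missed readings are the
dominant error mode of this kind of phenotype, and reviewers need to see
what the machine saw.

Value-range checks are *not* applied per token: outlier bounds apply to the
per-day mean (below), so the reject code `out_of_bounds_token` exists in the
audit vocabulary but is never produced by the default pipeline.

## Aggregation

Accepted readings are averaged per (patient, calendar day) — across notes of
the same day, not per note. The mean is computed after sorting values so it
is exactly permutation-invariant. Daily means strictly below 10% or above
90% are removed (10 and 90 kept): true EF outside that band is not
physiologically credible as a routine report and almost always indicates a
parsing artifact. One index EF per patient represents their current state;
the default policy is `latest` (subtype is a current clinical state), with
`earliest` and `nearest_to(date)` available; nearest ties break toward the
earlier date.

## Subtyping

EF < 40 → HFrEF; EF in [40, 50) → HFmrEF; EF ≥ 50 splits on NT-proBNP at
125 ng/l. Two open points were resolved as follows and are enforced in the
rule oracle test:

* **Exactly 125 ng/l counts as normal** (no HF): elevation is defined as
  strictly greater than the threshold, so the "≤ 125 normal" and "≥ 125
  elevated" readings of the guideline overlap resolve in favour of normal.
* **Missing NT-proBNP with EF ≥ 50 → `Indeterminate`**, not silently no-HF.
  Indeterminate patients are excluded (with counts) from validation and
  survival by default. NT-proBNP is irrelevant for EF < 50.

The EF 40–49 band is implemented as the half-open interval [40, 50) so that
non-integer daily means (49.5) classify as HFmrEF. NT-proBNP is paired to
the index EF date by minimal absolute day difference within ±365 days
(configurable), ties toward the earlier sample. Units are canonicalized on
ingest: NT-proBNP in ng/l (pg/ml ≡ ng/l), creatinine in µmol/l
(mg/dl × 88.42).

eGFR uses the CKD-EPI 2009 creatinine equation without the race coefficient:
141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 · 0.993^age · 1.018[female], κ =
0.7/0.9 and α = −0.329/−0.411 (female/male). Unit tests pin two values
computed independently from the closed form.

## Validation metrics

The 4×4 confusion matrix has algorithm labels as rows and gold labels as
columns. All metrics are one-vs-rest collapses (for "HF-any", positive =
any HF subtype): sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV
TP/(TP+FP), NPV TN/(TN+FN), accuracy (TP+TN)/n. Ratios with zero
denominator are reported as missing, never as zero. Display rounding is
half-up to integer percents; full precision is kept internally. EF-value
agreement reports exact matches, absolute difference within a tolerance
(default 5 EF percentage points — interpreted as points, not relative 5%),
and same-band agreement (<40, 40–49, ≥50).

## Survival model

Mortality is modelled with Cox proportional hazards on the **age time
scale**: subjects enter the risk set at their follow-up entry age (left
truncation) and exit at death or censoring. The fit is delegated to
lifelines' `CoxPHFitter` with `entry_col` (Efron tie handling, the common
default); 95% CIs are Wald intervals on the log scale. Terms: three subtype
indicators vs no-HF, plus sex, eGFR and five comorbidity flags.

Scaled Schoenfeld residuals are computed in-package because the backend does
not provide residuals under delayed entry. At each event age the residual is
the event subject's covariate vector minus the hazard-weighted covariate
mean over the left-truncated risk set; scaling follows Grambsch–Therneau
(d·I⁻¹r + β̂, the R convention that adds the coefficient). On untruncated
data the raw residuals agree with lifelines to machine precision (tested).
The proportionality check regresses each residual series on event age and
reports the slope's two-sided p-value.

Note one consequence of Efron ties: concatenating a dataset with an exact
copy of itself creates ties and therefore shifts the point estimate by a
small amount (~1% in tests) rather than leaving it bitwise identical;
precision still improves as expected.

## Synthetic-EHR generator

The generator emulates the study conditions, not the Finnish language or
real note style. Defaults, chosen once: subtype mix 3.4% HFrEF / 1.4%
HFmrEF / 6.2% HFpEF / 89% no HF (the published cohort prevalences); entry
age Normal(58.7, 18.2) truncated to [30, 90]; administrative censoring at
entry + Uniform(0, 3) years, giving a ~1.5-year mean follow-up; exponential
baseline hazard 0.05/year for the no-HF reference with multiplicative
subtype hazards 2.63 / 1.91 / 2.28 (the published point estimates as
generative truth) and modest covariate effects (male +0.3, eGFR −0.01 per
ml/min/1.73 m² centred at 90, flags +0.2 on the log scale); NT-proBNP
log-normal per subtype, capped at 125 ng/l for no-HF and floored at
126 ng/l for HFpEF so the biomarker is consistent with the generated label;
creatinine log-normal around 80 µmol/l. True EF is drawn uniformly on the
subtype band (15–39 / 40–49 / 50–75, integers); worded templates plant the
lexicon anchor value itself so truth and extraction can agree exactly.

Template kinds cover numeric, range, worded and multi-same-day mentions
plus three distractors (past reading, bare date near the trigger, non-EF
percentage). All randomness flows from one seed through a single generator,
so a fixed config is byte-reproducible.

What passing these tests shows: the extraction rules are internally
consistent, immune to the planted distractor classes, and the statistical
machinery recovers known generative parameters. What it does not show:
performance on real clinical narrative — actual notes contain vocabulary,
negations, cross-sentence temporal references and formatting the template
bank does not model, and real validation requires chart review.

## Problem sizes and numerics

The property suites use seeded corpora of 10,000 notes for extraction
fidelity and distractor robustness. Survival parameter recovery uses 100
replicates of n = 5,000 patients with the default (published) subtype mix;
coverage is assessed per replicate at ±3 SE, and the hazard-ratio ordering
HFrEF > HFpEF > HFmrEF is assessed on the mean fitted log-hazards across
replicates — at this prevalence the per-replicate standard error (~0.2 on
the log scale) exceeds the HFrEF–HFpEF separation (0.14), so the ordering
is a large-sample property, which the replicate mean estimates. Cox fits
require at least one event per modelled term and report separation or
non-convergence as diagnostic errors naming the term. Floating-point
equality for planted-vs-mined values uses a 1e-9 tolerance.

## Known limitations

No negation handling beyond the qualifier lists; no cross-sentence or
longitudinal reasoning; no adjudication when a day mixes correct and
incorrect readings (the audit trail exposes multi-mention days instead); no
competing risks or time-varying covariates in the survival model; the
shipped lexicon is English with a small phrase bank, and production use on
another language requires substituting the lexicon file.
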