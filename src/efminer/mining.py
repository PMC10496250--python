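"""Rule-based extraction of ejection-fraction values from clinical text.

The extractor follows a fixed cascade per sentence containing an EF
trigger term:

1. range patterns ("EF 35-40%") — collapsed to the interval midpoint;
2. numeric patterns ("EF 35%", "EF was 55 percent") — a two-digit
   integer part, optionally with a '.' or ',' decimal separator,
   followed by a percent marker or percent word;
3. only if neither produced an accepted candidate, a worded-description
   search ("EF preserved" -> 50%) using the lexicon map, longest phrase
   first.

Every candidate then passes quality checks: numeric tokens that are
part of a date-shaped string (e.g. "12.5.2019") are rejected as date
masquerades, and any sentence carrying a past-tense qualifier ("a year
ago", "previously", "in 2018") has all of its candidates rejected as
past readings.  Rejected candidates are kept, with reason codes, for
the audit trail.

Offsets are 0-based, half-open, relative to the sentence they index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .lexicon import Lexicon
from .types import (
    ClinicalNote,
    EFMention,
    MentionStatus,
    RejectReason,
    SourceKind,
)

__all__ = [
    "split_sentences",
    "find_triggers",
    "parse_numeric",
    "parse_range",
    "parse_worded",
    "apply_quality_checks",
    "extract_mentions",
]

_TERMINATORS = {".", "!", "?", "\n"}

# A two-digit integer part (not embedded in a longer number), optional
# decimal part with '.' or ',' separator.
_NUMBER = r"(?<![\d.,])(\d{2})(?:[.,](\d+))?(?!\d)"

# Date-shaped tokens: dd.mm.yyyy / dd/mm/yyyy / d.m.yy / trailing "dd.mm.",
# and a two-digit number immediately followed by a four-digit year.
_DATE_PATTERNS = [
    re.compile(r"(?<![\d.,])\d{1,2}\.\d{1,2}\.(?:\d{4}|\d{2})?(?!\d)"),
    re.compile(r"(?<![\d.,/])\d{1,2}/\d{1,2}/(?:\d{4}|\d{2})(?!\d)"),
    re.compile(r"(?<![\d.,])\d{2}\s+(?:19|20)\d{2}(?!\d)"),
]


def split_sentences(text: str) -> list[tuple[int, int, str]]:
    """Split free text into sentences with character offsets.

    Terminators are '.', '!', '?' and newline, except that a period
    flanked by digits (decimal separators, Finnish-style dates such as
    "12.5.2019") does not terminate.  Returns ``(start, end, sentence)``
    triples, whitespace-trimmed, in order.
    """
    boundaries = []
    for i, ch in enumerate(text):
        if ch not in _TERMINATORS:
            continue
        if (
            ch == "."
            and 0 < i < len(text) - 1
            and text[i - 1].isdigit()
            and text[i + 1].isdigit()
        ):
            continue
        boundaries.append(i)

    sentences = []
    start = 0
    for b in boundaries + [len(text)]:
        chunk = text[start:b]
        lead = len(chunk) - len(chunk.lstrip())
        stripped = chunk.strip()
        if stripped:
            s = start + lead
            sentences.append((s, s + len(stripped), stripped))
        start = b + 1
    return sentences


def find_triggers(sentence: str, lexicon: Lexicon) -> list[tuple[int, int]]:
    """Locate EF trigger terms in a sentence.

    Single-token triggers (e.g. "EF") match case-sensitively at word
    boundaries; multi-word triggers match case-insensitively.
    Overlapping hits are deduplicated to the longest match.
    """
    hits: list[tuple[int, int]] = []
    for term in lexicon.triggers:
        flags = re.IGNORECASE if " " in term else 0
        pattern = re.compile(r"\b" + re.escape(term) + r"\b", flags)
        hits.extend(m.span() for m in pattern.finditer(sentence))
    hits.sort(key=lambda s: (s[0], -(s[1] - s[0])))
    kept: list[tuple[int, int]] = []
    for span in hits:
        if any(span[0] >= k[0] and span[1] <= k[1] for k in kept):
            continue
        kept.append(span)
    return kept


@dataclass(frozen=True)
class _Candidate:
    span: tuple[int, int]
    kind: SourceKind
    low: float
    high: float


def _to_float(int_part: str, dec_part: str | None) -> float:
    return float(int_part if dec_part is None else f"{int_part}.{dec_part}")


def _percent_tail(lexicon: Lexicon) -> str:
    words = "|".join(re.escape(w) for w in lexicon.percent_words)
    return r"(?:\s*%|\s+(?:" + words + r")\b)"


def _search_regions(
    sentence: str, trigger_span: tuple[int, int], left_tokens: int
) -> list[tuple[int, int]]:
    """Rightward from the trigger, plus a small window just left of it
    (catches constructions like "35% EF")."""
    regions = [(trigger_span[1], len(sentence))]
    if left_tokens > 0:
        prefix = sentence[: trigger_span[0]]
        tokens = list(re.finditer(r"\S+", prefix))
        if tokens:
            regions.append((tokens[-left_tokens:][0].start(), trigger_span[0]))
    return regions


def parse_range(
    sentence: str,
    trigger_span: tuple[int, int],
    lexicon: Lexicon | None = None,
    left_tokens: int = 2,
) -> list[_Candidate]:
    """Find EF ranges like "35-40%" near the trigger.

    A percent marker may sit on either endpoint or both; at least one is
    required.  The candidate value is the interval midpoint.
    """
    lexicon = lexicon or Lexicon()
    tail = _percent_tail(lexicon)
    number1 = r"(?<![\d.,])(?P<i1>\d{2})(?:[.,](?P<d1>\d+))?(?!\d)"
    number2 = r"(?<![\d.,])(?P<i2>\d{2})(?:[.,](?P<d2>\d+))?(?!\d)"
    pattern = re.compile(
        number1 + r"(?P<p1>\s*%)?\s*[-–]\s*" + number2 + r"(?P<p2>" + tail + r")?",
        re.IGNORECASE,
    )
    out = []
    for lo_r, hi_r in _search_regions(sentence, trigger_span, left_tokens):
        for m in pattern.finditer(sentence, lo_r, hi_r):
            if m.group("p1") is None and m.group("p2") is None:
                continue
            low = _to_float(m.group("i1"), m.group("d1"))
            high = _to_float(m.group("i2"), m.group("d2"))
            out.append(_Candidate(m.span(), SourceKind.RANGE, low, high))
    out.sort(key=lambda c: c.span)
    return out


def parse_numeric(
    sentence: str,
    trigger_span: tuple[int, int],
    lexicon: Lexicon | None = None,
    left_tokens: int = 2,
    exclude: list[tuple[int, int]] | None = None,
) -> list[_Candidate]:
    """Find single numeric EF values ("35%", "55 percent") near the trigger.

    ``exclude`` spans (matched ranges) suppress numeric sub-matches of
    their own digits.
    """
    lexicon = lexicon or Lexicon()
    pattern = re.compile(_NUMBER + _percent_tail(lexicon), re.IGNORECASE)
    exclude = exclude or []
    out = []
    for lo_r, hi_r in _search_regions(sentence, trigger_span, left_tokens):
        for m in pattern.finditer(sentence, lo_r, hi_r):
            num_end = m.end(2) if m.group(2) else m.end(1)
            span = (m.start(1), num_end)
            if any(span[0] < e and span[1] > s for s, e in exclude):
                continue
            value = _to_float(m.group(1), m.group(2))
            out.append(_Candidate(span, SourceKind.NUMERIC, value, value))
    out.sort(key=lambda c: c.span)
    return out


def parse_worded(
    sentence: str, trigger_span: tuple[int, int], lexicon: Lexicon
) -> list[_Candidate]:
    """Map worded EF descriptions ("preserved", "mildly reduced") to percents.

    Longest phrase wins: a span claimed by "mildly reduced" cannot also
    fire "reduced".  Intended to run only when no accepted numeric or
    range candidate exists in the sentence.
    """
    claimed: list[tuple[int, int]] = []
    out = []
    for phrase, value in lexicon.worded_phrases_by_length():
        pattern = re.compile(r"\b" + re.escape(phrase) + r"\b", re.IGNORECASE)
        for m in pattern.finditer(sentence):
            span = m.span()
            if any(span[0] < e and span[1] > s for s, e in claimed):
                continue
            claimed.append(span)
            out.append(_Candidate(span, SourceKind.WORDED, value, value))
    out.sort(key=lambda c: c.span)
    return out


def _date_spans(sentence: str) -> list[tuple[int, int]]:
    spans = []
    for pattern in _DATE_PATTERNS:
        spans.extend(m.span() for m in pattern.finditer(sentence))
    return spans


def _has_past_qualifier(sentence: str, lexicon: Lexicon) -> bool:
    low = sentence.lower()
    if any(q.lower() in low for q in lexicon.past_qualifiers):
        return True
    if lexicon.past_year_pattern and re.search(r"\bin\s+(?:19|20)\d{2}\b", low):
        return True
    return False


def apply_quality_checks(
    mention: EFMention, sentence: str, lexicon: Lexicon
) -> EFMention:
    """Apply the date-masquerade and past-reading disqualification rules.

    Out-of-range values are *not* rejected here; outlier bounds apply to
    the per-day mean downstream.
    """
    if _has_past_qualifier(sentence, lexicon):
        return replace(
            mention,
            status=MentionStatus.REJECTED,
            reject_reason=RejectReason.PAST_READING,
        )
    if mention.source_kind is SourceKind.NUMERIC:
        s, e = mention.span
        if any(s < de and e > ds for ds, de in _date_spans(sentence)):
            return replace(
                mention,
                status=MentionStatus.REJECTED,
                reject_reason=RejectReason.DATE_MASQUERADE,
            )
    return mention


def _make_mention(note: ClinicalNote, sentence: str, cand: _Candidate) -> EFMention:
    return EFMention(
        patient_id=note.patient_id,
        note_id=note.note_id,
        note_date=note.note_date,
        sentence=sentence,
        span=cand.span,
        source_kind=cand.kind,
        raw_value_low=cand.low,
        raw_value_high=cand.high,
        resolved_value=(cand.low + cand.high) / 2.0,
        status=MentionStatus.ACCEPTED,
        reject_reason=RejectReason.NONE,
    )


def extract_mentions(
    note: ClinicalNote, lexicon: Lexicon | None = None, left_tokens: int = 2
) -> list[EFMention]:
    """Run the full extraction cascade on one note.

    Emits every candidate, accepted or rejected, in sentence order; the
    worded fallback fires only in sentences where no numeric or range
    candidate survived the quality checks.
    """
    lexicon = lexicon or Lexicon()
    mentions: list[EFMention] = []
    for _, _, sentence in split_sentences(note.text):
        triggers = find_triggers(sentence, lexicon)
        if not triggers:
            continue
        seen: set[tuple[int, int]] = set()
        ranges: list[_Candidate] = []
        numerics: list[_Candidate] = []
        for tspan in triggers:
            for cand in parse_range(sentence, tspan, lexicon, left_tokens):
                if cand.span not in seen:
                    seen.add(cand.span)
                    ranges.append(cand)
            range_spans = [c.span for c in ranges]
            for cand in parse_numeric(
                sentence, tspan, lexicon, left_tokens, exclude=range_spans
            ):
                if cand.span not in seen:
                    seen.add(cand.span)
                    numerics.append(cand)

        checked = [
            apply_quality_checks(_make_mention(note, sentence, c), sentence, lexicon)
            for c in sorted(ranges + numerics, key=lambda c: c.span)
        ]
        any_accepted = any(m.status is MentionStatus.ACCEPTED for m in checked)
        if not any_accepted:
            for cand in parse_worded(sentence, triggers[0], lexicon):
                checked.append(
                    apply_quality_checks(
                        _make_mention(note, sentence, cand), sentence, lexicon
                    )
                )
        mentions.extend(sorted(checked, key=lambda m: m.span))
    return mentions
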