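# Default English lexicon for EF mining.
#
# The three worded anchors map to the 2016 ESC guideline bands:
# "preserved" -> 50, "mildly reduced" -> 45, "reduced" -> 39.
# "severely reduced" and "normal" are artifact-defined extras chosen on
# clinical grounds; replace this file to localise the vocabulary.
locale: en
triggers:
  - EF
  - ejection fraction
percent_words:
  - percent
worded_map:
  preserved: 50
  mildly reduced: 45
  reduced: 39
  severely reduced: 25
  normal: 60
past_qualifiers:
  - a year ago
  - years ago
  - months ago
  - previously
  - at the time
# Also treat "in <4-digit year>" as a past qualifier.
past_year_pattern: true
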