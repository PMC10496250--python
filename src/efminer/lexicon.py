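"""Lexicon: the configurable vocabulary driving EF text mining.

A lexicon bundles the trigger terms ("EF", "ejection fraction"), the
percent words, the worded-description map (e.g. "preserved" -> 50%), and
the past-tense qualifier phrases used to disqualify historical readings.
Lexicons live in YAML files so the vocabulary can be localised without
touching code; the shipped default is English.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .types import SchemaError


@dataclass(frozen=True)
class Lexicon:
    triggers: tuple[str, ...] = ("EF", "ejection fraction")
    percent_words: tuple[str, ...] = ("percent",)
    worded_map: dict = field(
        default_factory=lambda: {
            "preserved": 50.0,
            "mildly reduced": 45.0,
            "reduced": 39.0,
            "severely reduced": 25.0,
            "normal": 60.0,
        }
    )
    past_qualifiers: tuple[str, ...] = (
        "a year ago",
        "years ago",
        "months ago",
        "previously",
        "at the time",
    )
    #: When true, "in <4-digit year>" also counts as a past qualifier.
    past_year_pattern: bool = True
    locale: str = "en"

    def __post_init__(self):
        if not self.triggers:
            raise SchemaError("lexicon must define at least one trigger term")
        for phrase, value in self.worded_map.items():
            if not (0.0 <= float(value) <= 100.0):
                raise SchemaError(
                    f"worded_map value for {phrase!r} outside [0, 100]: {value}"
                )

    def worded_phrases_by_length(self) -> list[tuple[str, float]]:
        """Phrases longest-first so "mildly reduced" wins over "reduced"."""
        return sorted(
            ((p, float(v)) for p, v in self.worded_map.items()),
            key=lambda pv: (-len(pv[0]), pv[0]),
        )


def load_lexicon(source) -> Lexicon:
    """Load a lexicon from a YAML file path or file-like object."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("lexicon file must contain a mapping")
    known = {
        "triggers",
        "percent_words",
        "worded_map",
        "past_qualifiers",
        "past_year_pattern",
        "locale",
    }
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown lexicon keys: {sorted(unknown)}")
    kwargs = {}
    if "triggers" in raw:
        kwargs["triggers"] = tuple(raw["triggers"])
    if "percent_words" in raw:
        kwargs["percent_words"] = tuple(raw["percent_words"])
    if "worded_map" in raw:
        kwargs["worded_map"] = {str(k): float(v) for k, v in raw["worded_map"].items()}
    if "past_qualifiers" in raw:
        kwargs["past_qualifiers"] = tuple(raw["past_qualifiers"])
    if "past_year_pattern" in raw:
        kwargs["past_year_pattern"] = bool(raw["past_year_pattern"])
    if "locale" in raw:
        kwargs["locale"] = str(raw["locale"])
    return Lexicon(**kwargs)


def default_lexicon() -> Lexicon:
    """The shipped English lexicon (``lexicons/en.yaml``)."""
    ref = importlib.resources.files("efminer").joinpath("lexicons/en.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_lexicon(fh)
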