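import datetime as dt

import pytest

from efminer.lexicon import default_lexicon
from efminer.types import ClinicalNote


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture
def make_note():
    def _make(text, patient_id="p1", note_id="n1", date="2019-03-02"):
        return ClinicalNote(
            patient_id=patient_id,
            note_id=note_id,
            note_date=dt.date.fromisoformat(date),
            text=text,
        )

    return _make
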