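from datetime import date
from pathlib import Path

import pytest
from hypothesis import settings

from cannaphen.ehr import NoteRecord
from cannaphen.lexicon import default_lexicon
from cannaphen.simulate import generate_planted_study

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

INDEX_DATE = date(2015, 12, 31)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_note(text, pid="P1", nid="N1", when=INDEX_DATE):
    return NoteRecord(patient_id=pid, note_id=nid, note_date=when, text=text)


@pytest.fixture(scope="session")
def planted_study(tmp_path_factory) -> Path:
    """The exact-count synthetic study, generated once per session."""
    out = tmp_path_factory.mktemp("planted")
    generate_planted_study(out, seed=7)
    return out
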