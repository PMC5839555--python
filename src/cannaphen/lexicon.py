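"""Search lexicon definition and term-mention detection in clinical note text.

The phenotyping method rests on a deliberately simple premise: when a clinician
writes a specific psychoactive substance term ("marijuana", "cannabis", or the
local shorthand "mjx") into a progress note, the mention itself signals current
or former use.  Matching is therefore bare whole-word, case-insensitive string
search with **no** negation detection, section segmentation, or spelling
correction — "denies marijuana use" counts as a mention by design.

The abbreviation "mj" ships in the default lexicon but disabled: as a whole
word it is safe from "TMJ" (an interior substring never matches under the
word-boundary rule), but it collides with other two-letter abbreviations and
was judged too noisy.  Keeping it disabled-but-present makes the discard
decision auditable and togglable.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass
from datetime import date
from typing import TYPE_CHECKING
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .ehr import NoteRecord

__all__ = [
    "LexiconError",
    "LexiconTerm",
    "Lexicon",
    "Mention",
    "compile_lexicon",
    "default_lexicon",
    "load_lexicon",
    "find_mentions",
    "mentions_to_csv",
]

DEFAULT_LEXICON_RESOURCE = "default_lexicon.yaml"


class LexiconError(ValueError):
    """Invalid lexicon specification."""


@dataclass(frozen=True)
class LexiconTerm:
    """A single search term.

    ``surface`` is stored lowercase and must be a single token (no whitespace).
    ``enabled`` controls whether the term participates in matching; disabled
    terms are retained for documentation and opt-in use.  ``note`` records the
    rationale for inclusion or exclusion.
    """

    surface: str
    enabled: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not self.surface or not self.surface.strip():
            raise LexiconError("term surface must be non-empty")
        if any(ch.isspace() for ch in self.surface):
            raise LexiconError(f"term surface contains whitespace: {self.surface!r}")
        object.__setattr__(self, "surface", self.surface.lower())


@dataclass(frozen=True)
class Lexicon:
    """An ordered collection of terms plus the matching policy.

    Only ``whole_word`` matching is supported: a hit requires the characters
    immediately before and after the match to be absent or non-alphanumeric.
    Digits count as word characters, so "mjx2" does not contain "mjx" and
    "TMJ" does not contain "mj".
    """

    terms: tuple[LexiconTerm, ...]
    match_policy: str = "whole_word"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.match_policy != "whole_word":
            raise LexiconError(f"unsupported match policy: {self.match_policy!r}")
        surfaces = [t.surface for t in self.terms]
        dupes = {s for s in surfaces if surfaces.count(s) > 1}
        if dupes:
            raise LexiconError(f"duplicate term surfaces: {sorted(dupes)}")
        if not any(t.enabled for t in self.terms):
            raise LexiconError("lexicon must contain at least one enabled term")

    @property
    def enabled_surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.terms if t.enabled)

    def pattern(self) -> re.Pattern[str]:
        """Compiled alternation over enabled terms with word-boundary guards.

        Longest-first alternation so overlapping surfaces (e.g. a term that is
        a prefix of another) resolve to the longest hit at each position.
        """
        alts = sorted(self.enabled_surfaces, key=len, reverse=True)
        body = "|".join(re.escape(s) for s in alts)
        # [^\W_] == alphanumeric (unicode-aware); underscore is a boundary.
        pat = rf"(?<![^\W_])(?:{body})(?![^\W_])"
        flags = 0 if self.case_sensitive else re.IGNORECASE
        return re.compile(pat, flags)


@dataclass(frozen=True)
class Mention:
    """A located whole-word occurrence of a lexicon term in one note.

    Offsets are 0-based character positions into the NFC-normalized note text,
    with ``end`` exclusive; ``text[start:end] == matched_text`` and
    ``matched_text.lower() == term``.
    """

    patient_id: str
    note_id: str
    note_date: date
    term: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention offsets [{self.start}, {self.end})")
        if self.matched_text.lower() != self.term:
            raise ValueError(
                f"matched text {self.matched_text!r} does not fold to term {self.term!r}"
            )


def compile_lexicon(term_specs: Iterable[Mapping[str, object] | LexiconTerm]) -> Lexicon:
    """Build a :class:`Lexicon` from term definitions.

    Each spec is a ``LexiconTerm`` or a mapping with keys ``surface`` and
    optional ``enabled`` (default True) and ``note``.  Surfaces must be unique
    after lowercasing.
    """
    specs = list(term_specs)
    if not specs:
        raise LexiconError("term specification list is empty")
    terms = []
    for spec in specs:
        if isinstance(spec, LexiconTerm):
            terms.append(spec)
        else:
            terms.append(
                LexiconTerm(
                    surface=str(spec["surface"]),
                    enabled=bool(spec.get("enabled", True)),
                    note=str(spec.get("note", "")),
                )
            )
    return Lexicon(terms=tuple(terms))


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a YAML (or JSON — YAML superset) config file.

    Expected layout: a top-level ``terms`` list of ``{surface, enabled, note}``
    entries.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "terms" not in doc:
        raise LexiconError(f"{path}: expected a mapping with a 'terms' list")
    return compile_lexicon(doc["terms"])


def default_lexicon() -> Lexicon:
    """The packaged default: marijuana, cannabis, mjx enabled; mj disabled."""
    ref = resources.files("cannaphen.data").joinpath(DEFAULT_LEXICON_RESOURCE)
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return compile_lexicon(doc["terms"])


def find_mentions(note: "NoteRecord", lexicon: Lexicon) -> list[Mention]:
    """Locate every non-overlapping whole-word enabled-term hit in a note.

    Matching is case-insensitive (unless the lexicon says otherwise) over the
    NFC-normalized note text.  Hyphenation or line breaks inside a term are not
    bridged.  Negation context is deliberately not inspected.  Returns mentions
    sorted by start offset.
    """
    text = unicodedata.normalize("NFC", note.text)
    if not text:
        return []
    pattern = lexicon.pattern()
    out: list[Mention] = []
    for m in pattern.finditer(text):
        out.append(
            Mention(
                patient_id=note.patient_id,
                note_id=note.note_id,
                note_date=note.note_date,
                term=m.group(0).lower(),
                start=m.start(),
                end=m.end(),
                matched_text=m.group(0),
            )
        )
    return out


def mentions_to_csv(mentions: Sequence[Mention], path: str | Path) -> None:
    """Export mentions as CSV (patient_id,note_id,note_date,term,start,end,matched_text)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "note_id", "note_date", "term", "start", "end", "matched_text"]
        )
        for m in mentions:
            w.writerow(
                [m.patient_id, m.note_id, m.note_date.isoformat(), m.term, m.start, m.end, m.matched_text]
            )
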