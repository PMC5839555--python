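"""Patients, notes, and cohort selection.

The study design targets older adults with established coronary artery disease
(CAD): patients aged 65-67 with a CAD ICD-9 diagnosis and at least one primary
care visit during the index year, so the most recent documentation of
marijuana use is available.  This module holds the record types, JSONL/CSV
readers with per-line error reporting, and the pure cohort filter.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ParseError",
    "ConfigurationError",
    "NoteRecord",
    "PatientRecord",
    "CohortSpec",
    "DEFAULT_CAD_ROOTS",
    "select_cohort",
    "read_notes",
    "write_notes",
    "read_patients",
    "write_patients",
]

logger = logging.getLogger(__name__)

# ICD-9 lexical shape: 3 digits, V + 2 digits, or E + 3 digits; optional
# decimal with 1-2 digits.
_ICD9_RE = re.compile(r"^(\d{3}|V\d{2}|E\d{3})(\.\d{1,2})?$")

# The study names no specific CAD code list; the conventional ICD-9 CAD range
# is 410-414 (acute MI through other forms of chronic ischemic heart disease).
DEFAULT_CAD_ROOTS = frozenset({"410", "411", "412", "413", "414"})


class ParseError(ValueError):
    """Malformed input file; message carries the file, line, and field."""


class ConfigurationError(ValueError):
    """Invalid cohort or classifier configuration."""


@dataclass(frozen=True)
class NoteRecord:
    patient_id: str
    note_id: str
    note_date: date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        if not isinstance(self.note_date, date):
            raise TypeError("note_date must be a datetime.date")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age_years: int
    diagnosis_codes: frozenset[str] = frozenset()
    visit_dates: tuple[date, ...] = ()
    deceased: bool = False
    has_contact_info: bool = True

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        bad = [c for c in self.diagnosis_codes if not _ICD9_RE.match(c)]
        if bad:
            raise ValueError(f"codes not in ICD-9 lexical shape: {sorted(bad)}")
        object.__setattr__(self, "diagnosis_codes", frozenset(self.diagnosis_codes))
        object.__setattr__(self, "visit_dates", tuple(self.visit_dates))


@dataclass(frozen=True)
class CohortSpec:
    """Filter criteria: CAD diagnosis, age band, visit inside the index window.

    ``cad_codes`` may contain full codes ("414.01") or 3-character roots
    ("414"); a patient code matches if the code itself or its root is listed.
    Both window ends are inclusive.
    """

    cad_codes: frozenset[str] = DEFAULT_CAD_ROOTS
    age_min: int = 65
    age_max: int = 67
    visit_window_start: date = date(2015, 1, 1)
    visit_window_end: date = date(2015, 12, 31)

    def __post_init__(self) -> None:
        if not self.cad_codes:
            raise ConfigurationError("cad_codes must be non-empty")
        if self.age_min > self.age_max:
            raise ConfigurationError("age_min must be <= age_max")
        if self.visit_window_start > self.visit_window_end:
            raise ConfigurationError("visit window start must be <= end")
        object.__setattr__(self, "cad_codes", frozenset(self.cad_codes))


def _code_matches(code: str, cad_codes: frozenset[str]) -> bool:
    return code in cad_codes or code.split(".", 1)[0] in cad_codes


def has_cad(patient: PatientRecord, spec: CohortSpec) -> bool:
    return any(_code_matches(c, spec.cad_codes) for c in patient.diagnosis_codes)


def in_age_band(patient: PatientRecord, spec: CohortSpec) -> bool:
    return spec.age_min <= patient.age_years <= spec.age_max


def has_window_visit(patient: PatientRecord, spec: CohortSpec) -> bool:
    return any(
        spec.visit_window_start <= d <= spec.visit_window_end for d in patient.visit_dates
    )


def select_cohort(
    patients: Sequence[PatientRecord], spec: CohortSpec
) -> list[PatientRecord]:
    """Pure filter: CAD diagnosis AND age band AND >= 1 in-window visit.

    Input order is preserved; the result is always a subset of the input, and
    the filter is idempotent.
    """
    return [
        p
        for p in patients
        if has_cad(p, spec) and in_age_band(p, spec) and has_window_visit(p, spec)
    ]


def _parse_date(raw: str, where: str) -> date:
    try:
        return date.fromisoformat(raw)
    except ValueError as exc:
        raise ParseError(f"{where}: unparseable date {raw!r}") from exc


def read_notes(path: str | Path) -> list[NoteRecord]:
    """Read notes from JSONL: one object per line with keys
    patient_id, note_id, date, text."""
    path = Path(path)
    notes: list[NoteRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            where = f"{path.name}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{where}: invalid JSON") from exc
            for key in ("patient_id", "note_id", "date", "text"):
                if key not in obj:
                    raise ParseError(f"{where}: missing required field {key!r}")
            rec = NoteRecord(
                patient_id=str(obj["patient_id"]),
                note_id=str(obj["note_id"]),
                note_date=_parse_date(str(obj["date"]), where),
                text=str(obj["text"]),
            )
            key = (rec.patient_id, rec.note_id)
            if key in seen:
                raise ParseError(f"{where}: duplicate note_id {rec.note_id!r} "
                                 f"for patient {rec.patient_id!r}")
            seen.add(key)
            notes.append(rec)
    if not notes:
        logger.warning("%s: no notes parsed (empty file)", path)
    return notes


def write_notes(notes: Iterable[NoteRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": n.patient_id,
                        "note_id": n.note_id,
                        "date": n.note_date.isoformat(),
                        "text": n.text,
                    }
                )
                + "\n"
            )


_PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "diagnosis_codes",
    "visit_dates",
    "deceased",
    "has_contact_info",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read the patient registry CSV.

    Columns: patient_id, age_years, diagnosis_codes (semicolon-separated),
    visit_dates (semicolon-separated ISO dates), deceased, has_contact_info.
    """
    path = Path(path)
    patients: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty patient registry", path)
            return []
        missing = set(_PATIENT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path.name}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            try:
                codes = frozenset(
                    c for c in row["diagnosis_codes"].split(";") if c
                )
                visits = tuple(
                    _parse_date(d, where)
                    for d in row["visit_dates"].split(";")
                    if d
                )
                patients.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        age_years=int(row["age_years"]),
                        diagnosis_codes=codes,
                        visit_dates=visits,
                        deceased=_BOOL[row["deceased"].strip().lower()],
                        has_contact_info=_BOOL[row["has_contact_info"].strip().lower()],
                    )
                )
            except ParseError:
                raise
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{where}: {exc}") from exc
    if not patients:
        logger.warning("%s: no patients parsed (empty file)", path)
    return patients


def write_patients(patients: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PATIENT_COLUMNS)
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    p.age_years,
                    ";".join(sorted(p.diagnosis_codes)),
                    ";".join(d.isoformat() for d in p.visit_dates),
                    str(p.deceased).lower(),
                    str(p.has_contact_info).lower(),
                ]
            )
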