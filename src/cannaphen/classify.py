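"""The core search algorithm: preliminary user / non-user classification.

A cohort patient is a *preliminary user* if any enabled lexicon term occurs as
a whole-word mention in any of their notes dated within a 12-month lookback
window, and a *preliminary non-user* otherwise.  "Past 12 months" means the
365 calendar days ending at and including the index date, i.e. the closed
interval [index_date - 364 days, index_date].  The label is preliminary by
construction — a mention is evidence of current or former use, and the
definitive exposure assessment comes from the follow-up interview.

Arm sampling mirrors the study sequence: draw n per arm uniformly without
replacement with a seeded generator, *then* exclude deceased patients and set
aside those without contact information.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ehr import ConfigurationError, NoteRecord, ParseError, PatientRecord
from .lexicon import Lexicon, Mention, find_mentions

__all__ = [
    "Label",
    "Classification",
    "ArmSample",
    "classify_patient",
    "classify_cohort",
    "sample_arms",
    "classifications_to_csv",
    "read_classifications",
]

logger = logging.getLogger(__name__)


class Label(str, Enum):
    PRELIMINARY_USER = "preliminary_user"
    PRELIMINARY_NONUSER = "preliminary_nonuser"


@dataclass(frozen=True)
class Classification:
    """Per-patient outcome of the lookback term search."""

    patient_id: str
    label: Label
    supporting_mentions: tuple[Mention, ...]
    index_date: date
    lookback_days: int = 365

    def __post_init__(self) -> None:
        if self.lookback_days <= 0:
            raise ConfigurationError("lookback_days must be positive")
        expected = (
            Label.PRELIMINARY_USER if self.supporting_mentions else Label.PRELIMINARY_NONUSER
        )
        if self.label is not expected:
            raise ValueError("label inconsistent with supporting mentions")
        start = self.index_date - timedelta(days=self.lookback_days - 1)
        for m in self.supporting_mentions:
            if not (start <= m.note_date <= self.index_date):
                raise ValueError(
                    f"supporting mention dated {m.note_date} outside lookback "
                    f"window [{start}, {self.index_date}]"
                )


def _window_start(index_date: date, lookback_days: int) -> date:
    return index_date - timedelta(days=lookback_days - 1)


def classify_patient(
    patient_id: str,
    notes: Sequence[NoteRecord],
    lexicon: Lexicon,
    index_date: date,
    lookback_days: int = 365,
) -> Classification:
    """Classify one patient from their notes.

    Only notes dated inside the lookback window are searched; out-of-window
    mentions are neither counted nor retained.  A patient with no notes is a
    preliminary non-user (absence of evidence is the study's operational
    definition of non-use).
    """
    if lookback_days <= 0:
        raise ConfigurationError("lookback_days must be positive")
    foreign = [n.note_id for n in notes if n.patient_id != patient_id]
    if foreign:
        raise ValueError(f"notes {foreign} do not belong to patient {patient_id!r}")
    start = _window_start(index_date, lookback_days)
    mentions: list[Mention] = []
    for note in notes:
        if start <= note.note_date <= index_date:
            mentions.extend(find_mentions(note, lexicon))
    mentions.sort(key=lambda m: (m.note_date, m.note_id, m.start))
    label = Label.PRELIMINARY_USER if mentions else Label.PRELIMINARY_NONUSER
    return Classification(
        patient_id=patient_id,
        label=label,
        supporting_mentions=tuple(mentions),
        index_date=index_date,
        lookback_days=lookback_days,
    )


def classify_cohort(
    cohort: Sequence[PatientRecord],
    notes: Sequence[NoteRecord],
    lexicon: Lexicon,
    index_date: date,
    lookback_days: int = 365,
) -> list[Classification]:
    """Classify every cohort patient; notes for non-cohort patients are
    ignored with a warning, and patients with zero notes are classified
    (as non-users), not dropped."""
    ids = [p.patient_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort patient_ids are not unique")
    by_patient: dict[str, list[NoteRecord]] = {pid: [] for pid in ids}
    n_orphan = 0
    for note in notes:
        if note.patient_id in by_patient:
            by_patient[note.patient_id].append(note)
        else:
            n_orphan += 1
    if n_orphan:
        logger.warning("ignored %d notes referencing patients outside the cohort", n_orphan)
    return [
        classify_patient(pid, by_patient[pid], lexicon, index_date, lookback_days)
        for pid in ids
    ]


@dataclass(frozen=True)
class ArmSample:
    """The two sampled study arms after post-sampling exclusions.

    ``users`` / ``nonusers`` are the retained ids; ``excluded_deceased`` were
    drawn but removed; ``excluded_no_contact`` are retained in the arms'
    accounting narrative only up to the contact step — they cannot be
    recruited.  The seed is recorded for reproducibility.
    """

    users: tuple[str, ...]
    nonusers: tuple[str, ...]
    excluded_deceased: tuple[str, ...]
    excluded_no_contact: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.users) & set(self.nonusers):
            raise ValueError("users and nonusers overlap")
        retained = set(self.users) | set(self.nonusers)
        if retained & set(self.excluded_deceased):
            raise ValueError("deceased exclusions overlap retained arms")

    @property
    def contactable(self) -> tuple[str, ...]:
        drop = set(self.excluded_no_contact)
        return tuple(pid for pid in self.users + self.nonusers if pid not in drop)


def sample_arms(
    classifications: Sequence[Classification],
    patients: Sequence[PatientRecord],
    n_per_arm: int = 51,
    seed: int = 0,
) -> ArmSample:
    """Draw ``n_per_arm`` ids from each preliminary arm, then apply exclusions.

    Sampling is uniform without replacement via ``numpy.random.default_rng``.
    Exclusion order follows the study narrative: sample first, then remove
    deceased patients, then flag patients lacking contact information.
    """
    by_id: Mapping[str, PatientRecord] = {p.patient_id: p for p in patients}
    users = [c.patient_id for c in classifications if c.label is Label.PRELIMINARY_USER]
    nonusers = [
        c.patient_id for c in classifications if c.label is Label.PRELIMINARY_NONUSER
    ]
    for name, arm in (("user", users), ("nonuser", nonusers)):
        if len(arm) < n_per_arm:
            raise ValueError(
                f"{name} arm has {len(arm)} members, fewer than n_per_arm={n_per_arm}"
            )
    rng = np.random.default_rng(seed)
    drawn_users = [users[i] for i in rng.choice(len(users), size=n_per_arm, replace=False)]
    drawn_nonusers = [
        nonusers[i] for i in rng.choice(len(nonusers), size=n_per_arm, replace=False)
    ]

    def is_deceased(pid: str) -> bool:
        return pid in by_id and by_id[pid].deceased

    def no_contact(pid: str) -> bool:
        return pid in by_id and not by_id[pid].has_contact_info

    deceased = [pid for pid in drawn_users + drawn_nonusers if is_deceased(pid)]
    kept_users = tuple(pid for pid in drawn_users if not is_deceased(pid))
    kept_nonusers = tuple(pid for pid in drawn_nonusers if not is_deceased(pid))
    no_contact_ids = tuple(pid for pid in kept_users + kept_nonusers if no_contact(pid))
    return ArmSample(
        users=kept_users,
        nonusers=kept_nonusers,
        excluded_deceased=tuple(deceased),
        excluded_no_contact=no_contact_ids,
        seed=seed,
    )


def classifications_to_csv(
    classifications: Sequence[Classification], path: str | Path
) -> None:
    """Write patient_id,label,n_supporting_mentions,first_mention_date."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "label", "n_supporting_mentions", "first_mention_date"])
        for c in classifications:
            first = min((m.note_date for m in c.supporting_mentions), default=None)
            w.writerow(
                [
                    c.patient_id,
                    c.label.value,
                    len(c.supporting_mentions),
                    first.isoformat() if first else "",
                ]
            )


def read_classifications(path: str | Path) -> dict[str, Label]:
    """Read the label column back; mention details are not round-tripped."""
    path = Path(path)
    out: dict[str, Label] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out[row["patient_id"]] = Label(row["label"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    return out
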