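"""Synthetic EHR/interview study generator.

Real chart text cannot be shared, so every upstream module is exercised
against simulated data with a known latent truth.  Two generation modes are
provided:

* **Probabilistic** (:func:`generate_study`): each patient draws nested use
  flags (ever ⊇ past-year ⊇ past-30-day) and a *documentation* flag — a
  past-year user's chart carries an in-window term mention with probability
  ``p_documented_given_past_year_use``; anyone else's chart carries a
  (typically negated or historical) term with probability
  ``p_term_given_no_past_year_use``.  This is the mode for property tests and
  parameter recovery: the probability that a term-positive patient is a true
  past-year user follows Bayes' rule from the configured probabilities.

* **Exact-count planting** (:func:`generate_planted_study`): cohort size, arm
  split, exclusions, interview completions and concordance cells are planted
  as exact counts, so the full pipeline reproduces a printed validation table
  cell for cell.  The deceased / no-contact flags are planted on ids drawn by
  the same seeded arm-sampling routine the pipeline will re-run, which is what
  makes the downstream accounting (51+51 sampled, 3 deceased, 99 retained,
  97 contactable) recoverable at any seed.

Notes are short template sentences with slots for terms, negation cues, and
boundary-confuser tokens ("TMJ", "cannabinoid", "MJX2") that a whole-word
matcher must not hit.  Negated mentions ("Denies marijuana use.") are planted
deliberately: the search method counts them by design, and their effect on
false positives is a measurable, documented limitation.

A single global seed drives named sub-streams (registry, truth, notes,
sampling, interviews, exposures) so adding one generator stage does not
perturb the others.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .classify import classify_cohort, sample_arms
from .ehr import (
    NoteRecord,
    PatientRecord,
    write_notes,
    write_patients,
)
from .exposure import (
    ExposureRecord,
    FrequencyCategory,
    Mode,
    OtherMode,
    write_exposures,
)
from .lexicon import Lexicon, default_lexicon
from .validation import InterviewResponse, write_interviews

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedStudy",
    "PlantedCounts",
    "generate_study",
    "generate_planted_study",
    "generate_interviews",
    "analytic_ppv_past_year",
    "write_truth",
    "read_truth",
]

logger = logging.getLogger(__name__)

_CAD_CODES = ("410.01", "411.1", "412", "413.9", "414.01", "414.8")

# Representative days of use per year for each self-report frequency
# category; used only by the simulator when it needs a concrete
# days_used_past_year for a category.  Override via SimulationConfig.
DEFAULT_FREQUENCY_DAYS: Mapping[str, int] = {
    "daily": 365,
    "weekly_not_daily": 104,
    "two_three_per_month": 30,
    "less_often": 12,
    "none": 0,
}


def _load_templates() -> dict[str, list[str]]:
    ref = resources.files("cannaphen.data").joinpath("note_templates.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class TruthRecord:
    """Latent per-patient truth: actual use flags plus the documentation flag
    (whether the chart carries an in-window term mention)."""

    patient_id: str
    ever: bool
    past_year: bool
    past_30d: bool
    documented: bool

    def __post_init__(self) -> None:
        if self.past_30d and not self.past_year:
            raise ValueError("past_30d implies past_year")
        if self.past_year and not self.ever:
            raise ValueError("past_year implies ever")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the probabilistic study generator.

    The default prevalence and documentation probabilities are back-derived
    from the validation cross-tabulation of the target study population
    (older adults with coronary artery disease): they reproduce, in
    expectation, a ~30% term-positive rate with past-year PPV near 48% and
    past-month PPV near 43%.
    """

    n_patients: int = 210
    p_ever_use: float = 0.75
    p_past_year_given_ever: float = 0.30
    p_past_30d_given_past_year: float = 0.83
    p_documented_given_past_year_use: float = 0.63
    p_term_given_no_past_year_use: float = 0.20
    notes_per_patient: float = 3.0  # Poisson mean on top of one guaranteed note
    confounder_rate: float = 0.2
    negated_mention_rate: float = 0.15
    p_out_of_window_mention: float = 0.1
    p_deceased: float = 0.03
    p_no_contact: float = 0.02
    index_date: date = date(2015, 12, 31)
    lookback_days: int = 365
    seed: int = 0
    frequency_days: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_DAYS)
    )

    def __post_init__(self) -> None:
        probs = {
            "p_ever_use": self.p_ever_use,
            "p_past_year_given_ever": self.p_past_year_given_ever,
            "p_past_30d_given_past_year": self.p_past_30d_given_past_year,
            "p_documented_given_past_year_use": self.p_documented_given_past_year_use,
            "p_term_given_no_past_year_use": self.p_term_given_no_past_year_use,
            "confounder_rate": self.confounder_rate,
            "negated_mention_rate": self.negated_mention_rate,
            "p_out_of_window_mention": self.p_out_of_window_mention,
            "p_deceased": self.p_deceased,
            "p_no_contact": self.p_no_contact,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


def analytic_ppv_past_year(config: SimulationConfig) -> float:
    """P(past-year use | >= 1 in-window mention) by Bayes' rule, the value the
    simulated pipeline's measured PPV converges to at large n."""
    p_py = config.p_ever_use * config.p_past_year_given_ever
    p_pos = (
        p_py * config.p_documented_given_past_year_use
        + (1.0 - p_py) * config.p_term_given_no_past_year_use
    )
    return p_py * config.p_documented_given_past_year_use / p_pos


@dataclass
class SimulatedStudy:
    patients: list[PatientRecord]
    notes: list[NoteRecord]
    truths: list[TruthRecord]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_patients(self.patients, out / "patients.csv")
        write_notes(self.notes, out / "notes.jsonl")
        write_truth(self.truths, out / "truth.csv")


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(len(items)))]


def _window_date(rng: np.random.Generator, cfg: SimulationConfig) -> date:
    return cfg.index_date - timedelta(days=int(rng.integers(cfg.lookback_days)))


def _old_date(rng: np.random.Generator, cfg: SimulationConfig) -> date:
    off = cfg.lookback_days + int(rng.integers(35, 365))
    return cfg.index_date - timedelta(days=off)


def _mention_sentence(
    rng: np.random.Generator,
    templates: Mapping[str, list[str]],
    lexicon: Lexicon,
    negated: bool,
) -> str:
    term = _pick(rng, lexicon.enabled_surfaces)
    pool = templates["mention_negated"] if negated else templates["mention_affirmed"]
    return _pick(rng, pool).format(term=term)


def _note_text(
    rng: np.random.Generator,
    templates: Mapping[str, list[str]],
    cfg: SimulationConfig,
    extra: str | None = None,
) -> str:
    k = 1 + int(rng.integers(3))
    sentences = [_pick(rng, templates["background"]) for _ in range(k)]
    if rng.random() < cfg.confounder_rate:
        sentences.append(_pick(rng, templates["confounder"]))
    if extra is not None:
        sentences.insert(int(rng.integers(len(sentences) + 1)), extra)
    return " ".join(sentences)


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Probabilistic mode: sample latent truth, then emit a registry passing
    the cohort filters and notes realizing the documentation model.

    A ``documented`` patient gets exactly one in-window note carrying a term
    sentence (phrased as a negation with probability ``negated_mention_rate``
    — still a mention, by the search method's design).  Undocumented patients
    get no in-window term; any patient may additionally carry an
    out-of-window (historical) mention with ``p_out_of_window_mention``,
    which the 12-month classifier must ignore.  Fully reproducible from the
    seed.
    """
    cfg = config
    templates = _load_templates()
    lexicon = default_lexicon()
    rngs = _streams(cfg.seed, ["registry", "truth", "notes"])
    reg, tru, nts = rngs["registry"], rngs["truth"], rngs["notes"]

    patients: list[PatientRecord] = []
    truths: list[TruthRecord] = []
    notes: list[NoteRecord] = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:05d}"
        n_visits = 1 + int(reg.integers(3))
        visits = tuple(
            sorted(_window_date(reg, cfg) for _ in range(n_visits))
        )
        patients.append(
            PatientRecord(
                patient_id=pid,
                age_years=65 + int(reg.integers(3)),
                diagnosis_codes=frozenset({_pick(reg, _CAD_CODES)}),
                visit_dates=visits,
                deceased=bool(reg.random() < cfg.p_deceased),
                has_contact_info=bool(reg.random() >= cfg.p_no_contact),
            )
        )

        ever = bool(tru.random() < cfg.p_ever_use)
        past_year = ever and bool(tru.random() < cfg.p_past_year_given_ever)
        past_30d = past_year and bool(tru.random() < cfg.p_past_30d_given_past_year)
        p_doc = (
            cfg.p_documented_given_past_year_use
            if past_year
            else cfg.p_term_given_no_past_year_use
        )
        documented = bool(tru.random() < p_doc)
        truths.append(
            TruthRecord(
                patient_id=pid,
                ever=ever,
                past_year=past_year,
                past_30d=past_30d,
                documented=documented,
            )
        )

        n_notes = 1 + int(nts.poisson(cfg.notes_per_patient))
        mention_at = int(nts.integers(n_notes)) if documented else -1
        for j in range(n_notes):
            if j == mention_at:
                extra = _mention_sentence(
                    nts, templates, lexicon, negated=nts.random() < cfg.negated_mention_rate
                )
                note_date = _window_date(nts, cfg)
            elif nts.random() < cfg.p_out_of_window_mention:
                # historical mention outside the lookback; must not flip the label
                extra = _mention_sentence(nts, templates, lexicon, negated=False)
                note_date = _old_date(nts, cfg)
            else:
                extra = None
                note_date = (
                    _window_date(nts, cfg) if nts.random() < 0.8 else _old_date(nts, cfg)
                )
            notes.append(
                NoteRecord(
                    patient_id=pid,
                    note_id=f"{pid}-N{j + 1:02d}",
                    note_date=note_date,
                    text=_note_text(nts, templates, cfg, extra),
                )
            )
    return SimulatedStudy(patients=patients, notes=notes, truths=truths)


def generate_interviews(
    truths: Sequence[TruthRecord],
    completion_rate: float,
    misreport_rate: float = 0.0,
    seed: int = 0,
) -> list[InterviewResponse]:
    """Interview each patient: completes with ``completion_rate``; completed
    responses equal truth with each flag independently flipped at
    ``misreport_rate``, after which the recall-window nesting is re-imposed
    (a reported past-30-day use forces past-year and ever)."""
    for name, p in (("completion_rate", completion_rate), ("misreport_rate", misreport_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} is not a probability")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out: list[InterviewResponse] = []
    for t in truths:
        completed = bool(rng.random() < completion_rate)
        if not completed:
            out.append(
                InterviewResponse(
                    patient_id=t.patient_id,
                    completed=False,
                    used_past_30d=False,
                    used_past_year=False,
                    ever_used=False,
                )
            )
            continue
        flip = rng.random(3) < misreport_rate
        p30 = t.past_30d ^ bool(flip[0])
        py = t.past_year ^ bool(flip[1])
        ever = t.ever ^ bool(flip[2])
        py = py or p30
        ever = ever or py
        out.append(
            InterviewResponse(
                patient_id=t.patient_id,
                completed=True,
                used_past_30d=p30,
                used_past_year=py,
                ever_used=ever,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact-count planting


@dataclass(frozen=True)
class PlantedCounts:
    """Exact counts to plant; defaults are the study's narrative accounting.

    ``cells_*`` order: (past_30d, past_year, nonuse, ever) with the nesting
    past_30d <= past_year <= ever and ever + nonuse == completed for the arm.
    """

    n_cohort: int = 210
    n_decoys: int = 8  # registry rows that must fail the cohort filters
    n_term_positive: int = 62
    n_out_of_window_mentions: int = 5  # term-negative patients with old mentions
    n_per_arm: int = 51
    n_deceased_users: int = 1
    n_deceased_nonusers: int = 2
    n_no_contact_users: int = 1
    n_no_contact_nonusers: int = 1
    completed_term_positive: int = 35
    completed_term_negative: int = 34
    cells_term_positive: tuple[int, int, int, int] = (15, 17, 2, 33)
    cells_term_negative: tuple[int, int, int, int] = (3, 4, 11, 23)
    refused_by_message: int = 1
    refused_on_call: int = 20
    unreachable: int = 7
    # exposure pattern among the planted current (past-30-day) users
    n_predominantly_smoked: int = 16
    n_daily: int = 7
    n_weekly_not_daily: int = 2
    n_two_three_per_month: int = 1
    n_smokers_with_other_modes: int = 10

    def __post_init__(self) -> None:
        for cells, total in (
            (self.cells_term_positive, self.completed_term_positive),
            (self.cells_term_negative, self.completed_term_negative),
        ):
            p30, py, nonuse, ever = cells
            if not (p30 <= py <= ever <= total):
                raise ValueError(f"cells {cells} violate recall-window nesting")
            if ever + nonuse != total:
                raise ValueError(f"cells {cells}: ever + nonuse != {total}")
        if self.n_term_positive > self.n_cohort:
            raise ValueError("more term-positive patients than cohort members")
        n_contact_users = (
            self.n_per_arm - self.n_deceased_users - self.n_no_contact_users
        )
        n_contact_nonusers = (
            self.n_per_arm - self.n_deceased_nonusers - self.n_no_contact_nonusers
        )
        n_noncompleted = (
            n_contact_users
            - self.completed_term_positive
            + n_contact_nonusers
            - self.completed_term_negative
        )
        if n_noncompleted != (
            self.refused_by_message + self.refused_on_call + self.unreachable
        ):
            raise ValueError("refusal/unreachable counts do not absorb non-completers")

    @property
    def n_current_users(self) -> int:
        return self.cells_term_positive[0] + self.cells_term_negative[0]


def _assign_cells(
    rng: np.random.Generator, ids: Sequence[str], cells: tuple[int, int, int, int]
) -> list[InterviewResponse]:
    """Distribute completed interview ids over the overlapping categories.

    Layout: p30 past-30-day users, then (py - p30) past-year-only, then
    (ever - py) former users, then nonuse never-users; ids are shuffled first
    so category membership is not correlated with id order.
    """
    p30, py, _nonuse, ever = cells
    order = list(ids)
    rng.shuffle(order)  # type: ignore[arg-type]
    out = []
    for k, pid in enumerate(order):
        out.append(
            InterviewResponse(
                patient_id=pid,
                completed=True,
                used_past_30d=k < p30,
                used_past_year=k < py,
                ever_used=k < ever,
            )
        )
    return out


def generate_planted_study(
    out_dir: str | Path,
    seed: int = 0,
    counts: PlantedCounts = PlantedCounts(),
    config: SimulationConfig = SimulationConfig(),
) -> Path:
    """Exact-count mode: write a full study (patients.csv, notes.jsonl,
    truth.csv, interviews.csv, exposures.csv) whose pipeline run reproduces
    every planted count.

    The registry contains ``n_cohort`` qualifying patients plus ``n_decoys``
    rows that fail the cohort filters.  Exactly ``n_term_positive`` cohort
    patients carry an in-window mention; ``n_out_of_window_mentions``
    term-negative patients carry only historical mentions the classifier must
    ignore.  Deceased and no-contact flags are planted on ids drawn by the
    same seeded arm sampler the pipeline re-runs with this seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    templates = _load_templates()
    lexicon = default_lexicon()
    rngs = _streams(
        seed, ["registry", "notes", "flags", "interviews", "exposures"]
    )

    # --- registry: qualifying cohort + filter-failing decoys
    patients: list[PatientRecord] = []
    for i in range(counts.n_cohort):
        reg = rngs["registry"]
        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                age_years=65 + int(reg.integers(3)),
                diagnosis_codes=frozenset({_pick(reg, _CAD_CODES)}),
                visit_dates=tuple(
                    sorted(_window_date(reg, cfg) for _ in range(1 + int(reg.integers(3))))
                ),
            )
        )
    for i in range(counts.n_decoys):
        reg = rngs["registry"]
        fail_mode = i % 3
        patients.append(
            PatientRecord(
                patient_id=f"D{i + 1:04d}",
                age_years=64 if fail_mode == 0 else 66,
                diagnosis_codes=(
                    frozenset({"250.00"}) if fail_mode == 1 else frozenset({_pick(reg, _CAD_CODES)})
                ),
                visit_dates=() if fail_mode == 2 else (_window_date(reg, cfg),),
            )
        )

    # --- notes: first n_term_positive cohort ids (after shuffling) documented
    nts = rngs["notes"]
    cohort_ids = [p.patient_id for p in patients if p.patient_id.startswith("P")]
    shuffled = list(cohort_ids)
    nts.shuffle(shuffled)  # type: ignore[arg-type]
    positive_ids = set(shuffled[: counts.n_term_positive])
    old_mention_ids = set(
        shuffled[counts.n_term_positive : counts.n_term_positive + counts.n_out_of_window_mentions]
    )
    notes: list[NoteRecord] = []
    for pid in cohort_ids:
        n_notes = 2 + int(nts.integers(2))
        mention_at = int(nts.integers(n_notes)) if pid in positive_ids else -1
        old_at = int(nts.integers(n_notes)) if pid in old_mention_ids else -2
        for j in range(n_notes):
            if j == mention_at:
                extra = _mention_sentence(
                    nts, templates, lexicon, negated=nts.random() < cfg.negated_mention_rate
                )
                note_date = _window_date(nts, cfg)
            elif j == old_at:
                extra = _mention_sentence(nts, templates, lexicon, negated=False)
                note_date = _old_date(nts, cfg)
            else:
                extra = None
                note_date = _window_date(nts, cfg)
            notes.append(
                NoteRecord(
                    patient_id=pid,
                    note_id=f"{pid}-N{j + 1:02d}",
                    note_date=note_date,
                    text=_note_text(nts, templates, cfg, extra),
                )
            )

    # --- run the classifier + sampler exactly as the pipeline will
    cohort = [p for p in patients if p.patient_id.startswith("P")]
    classifications = classify_cohort(
        cohort, notes, lexicon, cfg.index_date, cfg.lookback_days
    )
    arms = sample_arms(classifications, patients, n_per_arm=counts.n_per_arm, seed=seed)
    if len(arms.users) != counts.n_per_arm or len(arms.nonusers) != counts.n_per_arm:
        raise AssertionError("internal: planting expects no pre-existing exclusions")

    # --- plant deceased / no-contact flags on drawn ids
    flg = rngs["flags"]
    drawn_users, drawn_nonusers = list(arms.users), list(arms.nonusers)
    dead = set(
        list(flg.choice(drawn_users, size=counts.n_deceased_users, replace=False))
        + list(flg.choice(drawn_nonusers, size=counts.n_deceased_nonusers, replace=False))
    )
    alive_users = [pid for pid in drawn_users if pid not in dead]
    alive_nonusers = [pid for pid in drawn_nonusers if pid not in dead]
    no_contact = set(
        list(flg.choice(alive_users, size=counts.n_no_contact_users, replace=False))
        + list(flg.choice(alive_nonusers, size=counts.n_no_contact_nonusers, replace=False))
    )
    patients = [
        replace(
            p,
            deceased=p.patient_id in dead,
            has_contact_info=p.patient_id not in no_contact,
        )
        for p in patients
    ]

    # --- interviews for the contactable sample
    ivr = rngs["interviews"]
    contact_users = [pid for pid in alive_users if pid not in no_contact]
    contact_nonusers = [pid for pid in alive_nonusers if pid not in no_contact]
    completed_u = list(
        ivr.choice(contact_users, size=counts.completed_term_positive, replace=False)
    )
    completed_n = list(
        ivr.choice(contact_nonusers, size=counts.completed_term_negative, replace=False)
    )
    interviews = _assign_cells(ivr, completed_u, counts.cells_term_positive)
    interviews += _assign_cells(ivr, completed_n, counts.cells_term_negative)
    non_completers = [
        pid
        for pid in contact_users + contact_nonusers
        if pid not in set(completed_u) | set(completed_n)
    ]
    ivr.shuffle(non_completers)  # type: ignore[arg-type]
    dispositions: dict[str, str] = {iv.patient_id: "completed" for iv in interviews}
    labels = (
        ["refused_by_message"] * counts.refused_by_message
        + ["refused_on_call"] * counts.refused_on_call
        + ["unreachable"] * counts.unreachable
    )
    for pid, disp in zip(non_completers, labels):
        dispositions[pid] = disp
        interviews.append(
            InterviewResponse(
                patient_id=pid,
                completed=False,
                used_past_30d=False,
                used_past_year=False,
                ever_used=False,
            )
        )
    interviews.sort(key=lambda iv: iv.patient_id)

    # --- latent truth: interview answers where known, arm-consistent defaults elsewhere
    iv_by_id = {iv.patient_id: iv for iv in interviews if iv.completed}
    truths = []
    for pid in cohort_ids:
        if pid in iv_by_id:
            iv = iv_by_id[pid]
            ever, py, p30 = iv.ever_used, iv.used_past_year, iv.used_past_30d
        elif pid in positive_ids:
            ever, py, p30 = True, True, False
        else:
            ever, py, p30 = False, False, False
        truths.append(
            TruthRecord(
                patient_id=pid,
                ever=ever,
                past_year=py,
                past_30d=p30,
                documented=pid in positive_ids,
            )
        )

    # --- exposures for the planted current users
    exp = rngs["exposures"]
    current = sorted(pid for pid, iv in iv_by_id.items() if iv.used_past_30d)
    exp_order = list(current)
    exp.shuffle(exp_order)  # type: ignore[arg-type]
    freq_plan = (
        [FrequencyCategory.DAILY] * counts.n_daily
        + [FrequencyCategory.WEEKLY_NOT_DAILY] * counts.n_weekly_not_daily
        + [FrequencyCategory.TWO_THREE_PER_MONTH] * counts.n_two_three_per_month
    )
    n_smokers = counts.n_predominantly_smoked
    freq_plan += [FrequencyCategory.LESS_OFTEN] * (n_smokers - len(freq_plan))
    records = []
    for k, pid in enumerate(exp_order):
        smoker = k < n_smokers
        freq = freq_plan[k] if smoker else FrequencyCategory.LESS_OFTEN
        days = int(cfg.frequency_days[freq.value])
        other: frozenset[OtherMode] = frozenset()
        if not smoker:
            other = frozenset({OtherMode.EDIBLE})
        elif k < counts.n_smokers_with_other_modes:
            other = frozenset({_pick(exp, list(OtherMode))})  # type: ignore[arg-type]
        records.append(
            ExposureRecord(
                patient_id=pid,
                primary_mode=Mode.SMOKED if smoker else Mode.OTHER,
                frequency_category=freq,
                joints_per_day=float(exp.choice([0.25, 0.5, 1.0, 2.0])) if smoker else 0.0,
                days_used_past_year=days,
                other_modes=other,
            )
        )
    records.sort(key=lambda r: r.patient_id)

    # --- write everything
    write_patients(patients, out / "patients.csv")
    write_notes(notes, out / "notes.jsonl")
    write_truth(truths, out / "truth.csv")
    write_interviews(interviews, out / "interviews.csv", dispositions=dispositions)
    write_exposures(records, out / "exposures.csv")
    return out


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "ever", "past_year", "past_30d", "documented"])
        for t in truths:
            w.writerow(
                [
                    t.patient_id,
                    str(t.ever).lower(),
                    str(t.past_year).lower(),
                    str(t.past_30d).lower(),
                    str(t.documented).lower(),
                ]
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    flags = {"true": True, "false": False}
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TruthRecord(
                    patient_id=row["patient_id"],
                    ever=flags[row["ever"]],
                    past_year=flags[row["past_year"]],
                    past_30d=flags[row["past_30d"]],
                    documented=flags[row["documented"]],
                )
            )
    return out
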