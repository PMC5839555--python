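"""End-to-end pipeline: classify -> sample -> validate -> report.

Runs the stages in study order and emits the intermediate artifacts plus a
human-readable report whose narrative mirrors the study accounting: cohort
size, arm split, sampling, exclusions, recruitment disposition, the
concordance table with predictive values, the enrichment statements, the
ever-use association test, and the exposure summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Any

from . import __version__
from .classify import (
    ArmSample,
    Classification,
    Label,
    classifications_to_csv,
    classify_cohort,
    sample_arms,
)
from .ehr import CohortSpec, read_notes, read_patients, select_cohort
from .exposure import (
    ExposureRecord,
    Mode,
    mean_joint_years,
    read_exposures,
    use_pattern_summary,
)
from .lexicon import default_lexicon, load_lexicon
from .validation import (
    ARM_TERM_NEGATIVE,
    ARM_TERM_POSITIVE,
    ConcordanceTable,
    Disposition,
    association_test,
    build_concordance,
    concordance_to_csv,
    disposition_from_interviews,
    enrichment,
    predictive_value,
    read_interviews,
    recruitment_rate,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    notes_path: str
    patients_path: str
    out_dir: str
    interviews_path: str | None = None
    exposures_path: str | None = None
    lexicon_path: str | None = None
    index_date: date = date(2015, 12, 31)
    lookback_days: int = 365
    n_per_arm: int = 51
    seed: int = 0

    def validate_paths(self) -> None:
        required = [self.notes_path, self.patients_path]
        optional = [self.interviews_path, self.exposures_path, self.lexicon_path]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise StageError(f"startup: input path does not exist: {p}")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    cohort_size: int
    n_term_positive: int
    n_term_negative: int
    arms: ArmSample
    n_retained: int
    n_contactable: int
    classifications: list[Classification]
    concordance: ConcordanceTable | None
    disposition: Disposition | None
    recruitment_rate_pct: float | None
    exposures: list[ExposureRecord]
    report: str


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # pragma: no cover - message plumbing
                raise StageError(f"{name}: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow; writes artifacts under ``config.out_dir``.

    Artifacts: classifications.csv, arms.json, table1.csv (when interviews
    are supplied), report.txt, run_manifest.json.  Intermediate outputs are
    retained even when a later stage fails.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = (
        load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    )
    patients = _stage("read_patients")(read_patients)(config.patients_path)
    notes = _stage("read_notes")(read_notes)(config.notes_path)

    cohort = _stage("select_cohort")(select_cohort)(patients, CohortSpec())
    logger.info("cohort: %d of %d registry patients qualify", len(cohort), len(patients))

    classifications = _stage("classify")(classify_cohort)(
        cohort, notes, lexicon, config.index_date, config.lookback_days
    )
    n_pos = sum(c.label is Label.PRELIMINARY_USER for c in classifications)
    n_neg = len(classifications) - n_pos
    logger.info("classification: %d preliminary users / %d non-users", n_pos, n_neg)
    classifications_to_csv(classifications, out / "classifications.csv")

    arms = _stage("sample")(sample_arms)(
        classifications, patients, n_per_arm=config.n_per_arm, seed=config.seed
    )
    n_retained = len(arms.users) + len(arms.nonusers)
    n_contactable = len(arms.contactable)
    logger.info(
        "sampling: %d + %d drawn, %d deceased excluded -> %d retained, %d contactable",
        config.n_per_arm,
        config.n_per_arm,
        len(arms.excluded_deceased),
        n_retained,
        n_contactable,
    )
    (out / "arms.json").write_text(
        json.dumps(
            {
                "seed": arms.seed,
                "users": list(arms.users),
                "nonusers": list(arms.nonusers),
                "excluded_deceased": list(arms.excluded_deceased),
                "excluded_no_contact": list(arms.excluded_no_contact),
            },
            indent=2,
        )
    )

    concordance = disposition = rate = None
    if config.interviews_path:
        responses, frame = _stage("read_interviews")(read_interviews)(
            config.interviews_path
        )
        concordance = _stage("concordance")(build_concordance)(
            classifications, responses
        )
        concordance_to_csv(concordance, out / "table1.csv")
        if "disposition" in frame.columns:
            disposition = _stage("disposition")(disposition_from_interviews)(frame)
            rate = recruitment_rate(disposition)

    exposures: list[ExposureRecord] = []
    if config.exposures_path:
        exposures = _stage("read_exposures")(read_exposures)(config.exposures_path)

    report = _render_report(
        config, len(cohort), n_pos, n_neg, arms, n_retained, n_contactable,
        concordance, disposition, rate, exposures,
    )
    (out / "report.txt").write_text(report)
    (out / "run_manifest.json").write_text(
        json.dumps(
            {
                "tool": "cannaphen",
                "version": __version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
            },
            indent=2,
        )
    )
    return PipelineResult(
        cohort_size=len(cohort),
        n_term_positive=n_pos,
        n_term_negative=n_neg,
        arms=arms,
        n_retained=n_retained,
        n_contactable=n_contactable,
        classifications=classifications,
        concordance=concordance,
        disposition=disposition,
        recruitment_rate_pct=rate,
        exposures=exposures,
        report=report,
    )


def _render_report(
    config: RunConfig,
    cohort_size: int,
    n_pos: int,
    n_neg: int,
    arms: ArmSample,
    n_retained: int,
    n_contactable: int,
    concordance: ConcordanceTable | None,
    disposition: Disposition | None,
    rate: float | None,
    exposures: list[ExposureRecord],
) -> str:
    lines = [
        f"cannaphen {__version__}  (seed={config.seed}, config={config.config_hash()})",
        f"generated: {datetime.now(timezone.utc).isoformat(timespec='seconds')}",
        "",
        "== Cohort and classification ==",
        f"Cohort patients passing filters: {cohort_size}",
        f"Preliminary users (term in notes, past {config.lookback_days} days): {n_pos}",
        f"Preliminary non-users (no term): {n_neg}",
        "",
        "== Arm sampling ==",
        f"Drawn per arm: {config.n_per_arm}",
        f"Deceased excluded after sampling: {len(arms.excluded_deceased)}",
        f"Retained: {len(arms.users)} potential users + "
        f"{len(arms.nonusers)} potential non-users = {n_retained}",
        f"Without contact information: {len(arms.excluded_no_contact)}",
        f"Contactable: {n_contactable}",
    ]
    if disposition is not None:
        lines += [
            "",
            "== Recruitment ==",
            f"Contacted: {disposition.contacted}",
            f"Refused by message: {disposition.refused_by_message}; "
            f"refused on call: {disposition.refused_on_call}; "
            f"unreachable: {disposition.unreachable}",
            f"Completed interviews: {disposition.completed}"
            + (f"  (recruitment rate {rate:.0f}%)" if rate is not None else ""),
        ]
    if concordance is not None:
        t = concordance
        lines += ["", "== Concordance (arm totals: "
                  f"{t.total(ARM_TERM_POSITIVE)} term-positive, "
                  f"{t.total(ARM_TERM_NEGATIVE)} term-negative) =="]
        for cat, label in (
            ("past_30d", "Use in past month"),
            ("past_year", "Use in past year"),
            ("nonuse", "Non-use (never)"),
            ("ever", "Ever use"),
        ):
            pos = t.cell(ARM_TERM_POSITIVE, cat)
            neg = t.cell(ARM_TERM_NEGATIVE, cat)
            ppos = predictive_value(t, ARM_TERM_POSITIVE, cat)
            pneg = predictive_value(t, ARM_TERM_NEGATIVE, cat)
            lines.append(f"{label:<22} {pos:>3} ({ppos}%)   {neg:>3} ({pneg}%)")
        for cat, label in (("past_30d", "past-month use"), ("ever", "lifetime ever use")):
            lo, hi = enrichment(t, cat)
            lines.append(
                f"Probability of {label} increased from {lo}% to {hi}% "
                "in patients with a term in their notes."
            )
        a = t.cell(ARM_TERM_POSITIVE, "ever")
        b = t.total(ARM_TERM_POSITIVE) - a
        c = t.cell(ARM_TERM_NEGATIVE, "ever")
        d = t.total(ARM_TERM_NEGATIVE) - c
        if 0 not in (a + b, c + d, a + c, b + d):
            odds, p = association_test(a, b, c, d, method="fisher_exact")
            lines.append(
                f"Ever-use association (Fisher exact, two-sided): OR={odds:.2f}, p={p:.4f}"
            )
    if exposures:
        current = [e for e in exposures]
        smokers = [e for e in current if e.primary_mode is Mode.SMOKED]
        summary = use_pattern_summary(current)
        lines += [
            "",
            "== Exposure among current users ==",
            f"Current users with exposure records: {len(current)}",
            f"Predominantly smoked: {len(smokers)} ({summary['predominantly_smoked']}%)",
            f"Daily: {summary['freq_daily']}%; weekly (not daily): "
            f"{summary['freq_weekly_not_daily']}%; 2-3/month: "
            f"{summary['freq_two_three_per_month']}%; less often: "
            f"{summary['freq_less_often']}%",
        ]
        if smokers:
            lines.append(
                f"Mean joint-years among current smokers: {mean_joint_years(smokers):.2f}"
            )
    return "\n".join(lines) + "\n"


def result_summary(result: PipelineResult) -> dict[str, Any]:
    """Flat numeric summary of a pipeline run (used by the CLI and scripts)."""
    out: dict[str, Any] = {
        "cohort_size": result.cohort_size,
        "n_term_positive": result.n_term_positive,
        "n_term_negative": result.n_term_negative,
        "n_deceased_excluded": len(result.arms.excluded_deceased),
        "n_retained_users": len(result.arms.users),
        "n_retained_nonusers": len(result.arms.nonusers),
        "n_retained": result.n_retained,
        "n_contactable": result.n_contactable,
    }
    if result.disposition is not None:
        out["n_completed"] = result.disposition.completed
        out["recruitment_rate_pct"] = result.recruitment_rate_pct
    if result.concordance is not None:
        t = result.concordance
        out["arm_total_term_positive"] = t.total(ARM_TERM_POSITIVE)
        out["arm_total_term_negative"] = t.total(ARM_TERM_NEGATIVE)
        for cat in ("past_30d", "past_year", "nonuse", "ever"):
            out[f"ppv_{cat}_pct"] = predictive_value(t, ARM_TERM_POSITIVE, cat)
            out[f"rate_{cat}_term_negative_pct"] = predictive_value(
                t, ARM_TERM_NEGATIVE, cat
            )
    return out
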