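"""Validation statistics: recruitment accounting, concordance, predictive values.

The phenotype is validated against interview self-report as the reference
standard.  The concordance table cross-tabulates the two preliminary arms
(term in notes in the past year / no term) against overlapping self-report
categories:

* ``past_30d``  — used marijuana in the past 30 days (current use)
* ``past_year`` — used in the past year (contains past_30d)
* ``ever``      — lifetime ever use (contains past_year)
* ``nonuse``    — no lifetime use; the complement of ``ever``, so
  ``ever + nonuse == arm_total`` in each arm

These rows are *not* a partition (a daily user appears in three of them),
which is why the table stores separate counters per category.

Positive predictive value is computed against each reference standard in
turn: the past-30-day PPV answers "if the chart carries a term, how likely is
the patient a *current* user?", the lifetime PPV answers the looser question.
Enrichment contrasts an outcome's prevalence across the two arms.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from scipy import stats

from ._rounding import percent, round_half_up
from .classify import Classification, Label
from .ehr import ParseError

__all__ = [
    "ARM_TERM_POSITIVE",
    "ARM_TERM_NEGATIVE",
    "CATEGORIES",
    "InterviewResponse",
    "Disposition",
    "ConcordanceTable",
    "recruitment_rate",
    "build_concordance",
    "predictive_value",
    "enrichment",
    "association_test",
    "group_summary",
    "read_interviews",
    "write_interviews",
    "disposition_from_interviews",
    "concordance_to_csv",
]

logger = logging.getLogger(__name__)

ARM_TERM_POSITIVE = "term_positive"
ARM_TERM_NEGATIVE = "term_negative"
ARMS = (ARM_TERM_POSITIVE, ARM_TERM_NEGATIVE)
CATEGORIES = ("past_30d", "past_year", "nonuse", "ever")

Category = Literal["past_30d", "past_year", "nonuse", "ever"]
Arm = Literal["term_positive", "term_negative"]


class DegenerateTableError(ValueError):
    """2x2 table with a zero margin; the test statistic is undefined."""


class UndefinedRateError(ZeroDivisionError):
    """Rate requested over an empty denominator."""


@dataclass(frozen=True)
class InterviewResponse:
    """Self-reported use flags from the telephone interview.

    Recall windows nest: past-30-day use implies past-year use implies ever
    use.  ``completed`` is False for refusals and unreachable patients, whose
    use flags are meaningless and must be False.
    """

    patient_id: str
    used_past_30d: bool
    used_past_year: bool
    ever_used: bool
    completed: bool = True

    def __post_init__(self) -> None:
        if self.used_past_30d and not self.used_past_year:
            raise ValueError(f"{self.patient_id}: past-30d use without past-year use")
        if self.used_past_year and not self.ever_used:
            raise ValueError(f"{self.patient_id}: past-year use without ever use")
        if not self.completed and self.ever_used:
            raise ValueError(f"{self.patient_id}: use flags set on a non-completed interview")


@dataclass(frozen=True)
class Disposition:
    """Per-outcome accounting of the recruitment telephone calls."""

    contacted: int
    completed: int
    refused_by_message: int
    refused_on_call: int
    unreachable: int

    def __post_init__(self) -> None:
        parts = (
            self.completed,
            self.refused_by_message,
            self.refused_on_call,
            self.unreachable,
        )
        if any(v < 0 for v in (self.contacted, *parts)):
            raise ValueError("disposition counts must be non-negative")
        if sum(parts) != self.contacted:
            raise ValueError(
                f"disposition does not balance: {'+'.join(map(str, parts))} "
                f"!= contacted={self.contacted}"
            )


def recruitment_rate(d: Disposition) -> float:
    """Completion percentage among patients called, as a whole-number percent
    (69 of 97 -> 71)."""
    if d.contacted == 0:
        raise UndefinedRateError("recruitment rate undefined: nobody contacted")
    return percent(d.completed, d.contacted, ndigits=0)


@dataclass(frozen=True)
class ConcordanceTable:
    """Arm-by-self-report-category counts (the validation cross-tabulation)."""

    counts: Mapping[str, Mapping[str, int]]
    arm_totals: Mapping[str, int]

    def __post_init__(self) -> None:
        for arm in ARMS:
            if arm not in self.counts or arm not in self.arm_totals:
                raise ValueError(f"missing arm {arm!r}")
            c = self.counts[arm]
            for cat in CATEGORIES:
                if c.get(cat, 0) < 0:
                    raise ValueError("negative cell count")
            if not (c["past_30d"] <= c["past_year"] <= c["ever"]):
                raise ValueError(f"{arm}: recall-window nesting violated")
            if c["ever"] + c["nonuse"] != self.arm_totals[arm]:
                raise ValueError(f"{arm}: ever + nonuse must equal the arm total")

    def cell(self, arm: str, category: str) -> int:
        return self.counts[arm][category]

    def total(self, arm: str) -> int:
        return self.arm_totals[arm]


def build_concordance(
    classifications: Sequence[Classification] | Mapping[str, Label],
    interviews: Sequence[InterviewResponse],
) -> ConcordanceTable:
    """Cross-tabulate preliminary arm against self-report categories.

    Only completed interviews contribute; every interviewed patient must have
    a classification.  Arm totals equal the number of completed interviews per
    arm, so all four category counts in an arm share one denominator.
    """
    if isinstance(classifications, Mapping):
        label_by_id = dict(classifications)
    else:
        label_by_id = {c.patient_id: c.label for c in classifications}
    unknown = sorted(
        {iv.patient_id for iv in interviews if iv.patient_id not in label_by_id}
    )
    if unknown:
        raise ValueError(f"interviews for unclassified patients: {unknown}")
    counts = {arm: {cat: 0 for cat in CATEGORIES} for arm in ARMS}
    totals = {arm: 0 for arm in ARMS}
    for iv in interviews:
        if not iv.completed:
            continue
        arm = (
            ARM_TERM_POSITIVE
            if label_by_id[iv.patient_id] is Label.PRELIMINARY_USER
            else ARM_TERM_NEGATIVE
        )
        totals[arm] += 1
        counts[arm]["past_30d"] += iv.used_past_30d
        counts[arm]["past_year"] += iv.used_past_year
        counts[arm]["ever"] += iv.ever_used
        counts[arm]["nonuse"] += not iv.ever_used
    return ConcordanceTable(counts=counts, arm_totals=totals)


def predictive_value(table: ConcordanceTable, arm: Arm, category: Category) -> float:
    """Percentage of the arm falling in the category, one-decimal half-up.

    For the term-positive arm this is the positive predictive value of the
    text search against the chosen reference standard.
    """
    total = table.total(arm)
    if total == 0:
        raise UndefinedRateError(f"arm {arm!r} has no completed interviews")
    return percent(table.cell(arm, category), total, ndigits=1)


def enrichment(table: ConcordanceTable, category: Category) -> tuple[float, float]:
    """(term-negative rate, term-positive rate) for a category, in the
    presentation order "increased from X% to Y%"."""
    return (
        predictive_value(table, ARM_TERM_NEGATIVE, category),
        predictive_value(table, ARM_TERM_POSITIVE, category),
    )


def _fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration.

    Conditions on both margins; sums P(table) over all tables whose point
    probability does not exceed the observed one (with a small relative
    tolerance for ties, the standard convention).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def log_pmf(x: int) -> float:
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    obs = log_pmf(a)
    cutoff = obs + 1e-7
    p = sum(math.exp(lp) for x in range(lo, hi + 1) if (lp := log_pmf(x)) <= cutoff)
    return min(p, 1.0)


def association_test(
    a: int,
    b: int,
    c: int,
    d: int,
    method: Literal["fisher_exact", "chi2", "chi2_yates"] = "fisher_exact",
) -> tuple[float, float]:
    """Test association in the 2x2 table [[a, b], [c, d]].

    ``fisher_exact`` returns (sample odds ratio, two-sided exact p) with the p
    computed by hypergeometric enumeration; ``chi2`` / ``chi2_yates`` return
    the Pearson statistic (without / with continuity correction) and its
    1-df chi-square p.  All margins must be positive.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if 0 in (a + b, c + d, a + c, b + d):
        raise DegenerateTableError("2x2 table has a zero margin")
    if method == "fisher_exact":
        odds = math.inf if b * c == 0 else (a * d) / (b * c)
        return odds, _fisher_exact_two_sided(a, b, c, d)
    if method in ("chi2", "chi2_yates"):
        res = stats.chi2_contingency(
            [[a, b], [c, d]], correction=(method == "chi2_yates")
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


def group_summary(
    data: pd.DataFrame, group_col: str = "current_use"
) -> pd.DataFrame:
    """Per-group descriptive summaries of covariates (no hypothesis tests).

    Boolean columns yield the percentage True; other categoricals yield one
    row per level with its percentage; numeric columns yield the mean.
    Returns a tidy frame with columns (covariate, level, statistic, plus one
    column per group).  Empty groups produce NaN with a warning.
    """
    if group_col not in data.columns:
        raise KeyError(f"grouping column {group_col!r} not in data")
    groups = sorted(data[group_col].dropna().unique(), reverse=True)
    rows = []
    for col in data.columns:
        if col == group_col or col == "patient_id":
            continue
        series = data[col]
        if pd.api.types.is_bool_dtype(series):
            stat_rows = [(col, "", "pct_true")]
        elif pd.api.types.is_numeric_dtype(series):
            stat_rows = [(col, "", "mean")]
        else:
            stat_rows = [(col, lvl, "pct") for lvl in sorted(series.dropna().unique())]
        for covariate, level, statistic in stat_rows:
            row: dict[str, object] = {
                "covariate": covariate,
                "level": level,
                "statistic": statistic,
            }
            for g in groups:
                sub = data.loc[data[group_col] == g, col].dropna()
                if len(sub) == 0:
                    logger.warning("empty group %r for covariate %r", g, col)
                    row[str(g)] = float("nan")
                elif statistic == "mean":
                    row[str(g)] = round_half_up(float(sub.mean()), 2)
                elif statistic == "pct_true":
                    row[str(g)] = percent(int(sub.sum()), len(sub))
                else:
                    row[str(g)] = percent(int((sub == level).sum()), len(sub))
            rows.append(row)
    return pd.DataFrame(rows)


_INTERVIEW_COLUMNS = ["patient_id", "completed", "used_past_30d", "used_past_year", "ever_used"]
_DISPOSITIONS = ("completed", "refused_by_message", "refused_on_call", "unreachable")

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_interviews(path: str | Path) -> tuple[list[InterviewResponse], pd.DataFrame]:
    """Read interviews.csv.

    Required columns: patient_id, completed, used_past_30d, used_past_year,
    ever_used.  Extra columns (disposition and covariates) are returned in the
    accompanying DataFrame untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(_INTERVIEW_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path.name}: missing columns {sorted(missing)}")
    responses = []
    for i, row in df.iterrows():
        try:
            responses.append(
                InterviewResponse(
                    patient_id=row["patient_id"],
                    completed=_coerce_bool(row["completed"]),
                    used_past_30d=_coerce_bool(row["used_past_30d"]),
                    used_past_year=_coerce_bool(row["used_past_year"]),
                    ever_used=_coerce_bool(row["ever_used"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path.name}:{i + 2}: {exc}") from exc
    return responses, df


def _coerce_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    return _BOOL[str(v).strip().lower()]


def write_interviews(
    responses: Iterable[InterviewResponse],
    path: str | Path,
    dispositions: Mapping[str, str] | None = None,
) -> None:
    """Write interviews.csv with an optional per-patient disposition column."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        cols = list(_INTERVIEW_COLUMNS) + (["disposition"] if dispositions else [])
        w = csv.writer(fh)
        w.writerow(cols)
        for r in responses:
            row = [
                r.patient_id,
                str(r.completed).lower(),
                str(r.used_past_30d).lower(),
                str(r.used_past_year).lower(),
                str(r.ever_used).lower(),
            ]
            if dispositions:
                row.append(dispositions.get(r.patient_id, "completed" if r.completed else "unreachable"))
            w.writerow(row)


def disposition_from_interviews(df: pd.DataFrame) -> Disposition:
    """Tally the disposition column of an interviews frame into a Disposition."""
    if "disposition" not in df.columns:
        raise ParseError("interviews file has no disposition column")
    counts = df["disposition"].value_counts().to_dict()
    unknown = set(counts) - set(_DISPOSITIONS)
    if unknown:
        raise ParseError(f"unknown disposition values: {sorted(unknown)}")
    return Disposition(
        contacted=int(len(df)),
        completed=int(counts.get("completed", 0)),
        refused_by_message=int(counts.get("refused_by_message", 0)),
        refused_on_call=int(counts.get("refused_on_call", 0)),
        unreachable=int(counts.get("unreachable", 0)),
    )


_ROW_LABELS = {
    "past_30d": "Self-reported use in the past month",
    "past_year": "Self-reported use in past year",
    "nonuse": "Self-report non-use",
    "ever": "Ever use",
}


def concordance_to_csv(table: ConcordanceTable, path: str | Path) -> None:
    """Write the concordance table with 'count (pct%)' cells, one row per
    self-report category and one column per arm."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "category",
                f"term_in_notes_past_year (n={table.total(ARM_TERM_POSITIVE)})",
                f"no_term_in_notes_past_year (n={table.total(ARM_TERM_NEGATIVE)})",
            ]
        )
        for cat in CATEGORIES:
            cells = []
            for arm in ARMS:
                n = table.cell(arm, cat)
                pct = predictive_value(table, arm, cat) if table.total(arm) else 0.0
                cells.append(f"{n} ({pct}%)")
            w.writerow([_ROW_LABELS[cat], *cells])
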