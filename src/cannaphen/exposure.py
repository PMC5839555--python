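"""Self-reported marijuana exposure quantification.

Exposure over the past year is expressed in *joint-years*, the marijuana
analogue of tobacco pack-years: one joint-year equals one joint per day for
365 days, so

    joint_years = joints_per_day * days_used / 365

Only smoked exposure has a joint equivalent; vaping, topicals and edibles are
recorded as modes but contribute no joint-years.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from ._rounding import percent

__all__ = [
    "Mode",
    "FrequencyCategory",
    "ExposureRecord",
    "joint_years",
    "mean_joint_years",
    "use_pattern_summary",
    "read_exposures",
    "write_exposures",
]


class Mode(str, Enum):
    SMOKED = "smoked"
    OTHER = "other"


class FrequencyCategory(str, Enum):
    DAILY = "daily"
    WEEKLY_NOT_DAILY = "weekly_not_daily"
    TWO_THREE_PER_MONTH = "two_three_per_month"
    LESS_OFTEN = "less_often"
    NONE = "none"


class OtherMode(str, Enum):
    VAPING = "vaping"
    TOPICAL = "topical"
    EDIBLE = "edible"


@dataclass(frozen=True)
class ExposureRecord:
    patient_id: str
    primary_mode: Mode
    frequency_category: FrequencyCategory
    joints_per_day: float
    days_used_past_year: int
    other_modes: frozenset[OtherMode] = frozenset()

    def __post_init__(self) -> None:
        if self.joints_per_day < 0:
            raise ValueError("joints_per_day must be non-negative")
        if not 0 <= self.days_used_past_year <= 365:
            raise ValueError("days_used_past_year must be in [0, 365]")
        if (self.days_used_past_year == 0) != (
            self.frequency_category is FrequencyCategory.NONE
        ):
            raise ValueError("days_used_past_year == 0 iff frequency category is none")
        object.__setattr__(self, "other_modes", frozenset(self.other_modes))

    @property
    def joint_years(self) -> float:
        return joint_years(self.joints_per_day, self.days_used_past_year)


def joint_years(joints_per_day: float, days_used: float, window_days: int = 365) -> float:
    """Cumulative exposure: joints_per_day * days_used / 365.

    ``days_used`` may not exceed the window length (365 for a one-year
    recall).  joint_years(1, 365) == 1.0 by definition, and the quantity is
    linear in each argument.
    """
    if joints_per_day < 0 or days_used < 0:
        raise ValueError("exposure inputs must be non-negative")
    if days_used > window_days:
        raise ValueError(f"days_used={days_used} exceeds the {window_days}-day window")
    return joints_per_day * days_used / 365


def mean_joint_years(records: Sequence[ExposureRecord]) -> float:
    """Arithmetic mean of per-record joint-years (restrict input to current
    smokers for the headline figure)."""
    if not records:
        raise ValueError("mean joint-years undefined on an empty record set")
    return sum(r.joint_years for r in records) / len(records)


def use_pattern_summary(records: Sequence[ExposureRecord]) -> dict[str, float]:
    """Distribution of use patterns among current users, in percent.

    Returns one ``freq_<category>`` entry per frequency category (a partition,
    so they sum to 100 up to rounding) plus ``predominantly_smoked``, the
    share whose primary mode is smoking.  One-decimal half-up rounding.
    """
    if not records:
        raise ValueError("use-pattern distribution undefined on empty input")
    n = len(records)
    out: dict[str, float] = {}
    for cat in FrequencyCategory:
        k = sum(r.frequency_category is cat for r in records)
        out[f"freq_{cat.value}"] = percent(k, n)
    out["predominantly_smoked"] = percent(
        sum(r.primary_mode is Mode.SMOKED for r in records), n
    )
    return out


_COLUMNS = [
    "patient_id",
    "primary_mode",
    "frequency_category",
    "joints_per_day",
    "days_used_past_year",
    "other_modes",
]


def write_exposures(records: Iterable[ExposureRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.primary_mode.value,
                    r.frequency_category.value,
                    r.joints_per_day,
                    r.days_used_past_year,
                    ";".join(sorted(m.value for m in r.other_modes)),
                ]
            )


def read_exposures(path: str | Path) -> list[ExposureRecord]:
    path = Path(path)
    out: list[ExposureRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out.append(
                    ExposureRecord(
                        patient_id=row["patient_id"],
                        primary_mode=Mode(row["primary_mode"]),
                        frequency_category=FrequencyCategory(row["frequency_category"]),
                        joints_per_day=float(row["joints_per_day"]),
                        days_used_past_year=int(row["days_used_past_year"]),
                        other_modes=frozenset(
                            OtherMode(m) for m in row["other_modes"].split(";") if m
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
    return out
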