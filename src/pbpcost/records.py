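"""Trainee-level training records and group-level descriptive summaries.

A :class:`TraineeRecord` captures one trainee's trajectory through a
simulation-based robotic-surgery curriculum: how many supervised training
trials they attempted, hands-on console time, billable laboratory days (on a
half-day grid — the lab invoices only full or half days), hotel nights, and
whether they reached the proficiency benchmark within the allotted training.

Four curricula are modelled, ordered by decreasing adherence to
proficiency-based progression (PBP): full PBP with a mandatory e-learning
benchmark (G1), e-learning without the benchmark (G2), traditional lectures
(G3), and a conventional apprenticeship without objective metrics (G4).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .money import round_half_up
from fractions import Fraction

GROUPS = ("G1_full_pbp", "G2_elearning", "G3_traditional", "G4_apprenticeship")

GROUP_LABELS: Mapping[str, str] = {
    "G1_full_pbp": "Group 1 (Full PBP)",
    "G2_elearning": "Group 2 (eLearning)",
    "G3_traditional": "Group 3 (Traditional)",
    "G4_apprenticeship": "Group 4 (Apprenticeship)",
}

#: Hard cap on billable laboratory time: training was limited to 3.5 days.
MAX_BILLED_DAYS = 3.5

#: Each training trial occupies at most a 30-minute console slot.
MAX_HOURS_PER_TRIAL = 0.5

COLUMNS = (
    "trainee_id",
    "group",
    "trials",
    "hands_on_hours",
    "billed_days",
    "nights",
    "proficient",
)

_HOURS_TOL = 1e-6
_GRID_TOL = 1e-9


class SchemaError(ValueError):
    """A tabular record file is missing a required column."""


class RecordValidationError(ValueError):
    """One or more rows violate the record invariants.

    ``errors`` holds ``(row_number, message)`` pairs, 1-based and counting
    the header as row 1, so the offending line can be located in the file.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        detail = "; ".join(f"row {r}: {m}" for r, m in self.errors)
        super().__init__(f"{len(self.errors)} invalid record(s): {detail}")


class EmptyGroupError(ValueError):
    """A group summary was requested for a group with no records."""


def _on_half_day_grid(days: float) -> bool:
    return abs(days * 2 - round(days * 2)) <= _GRID_TOL


@dataclass(frozen=True)
class TraineeRecord:
    """One trainee's training trajectory and billable resource use."""

    trainee_id: str
    group: str
    trials: int
    hands_on_hours: float
    billed_days: float
    nights: int
    proficient: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not isinstance(self.trials, int) or self.trials < 1:
            raise ValueError(f"trials must be a positive integer, got {self.trials!r}")
        if self.hands_on_hours < 0:
            raise ValueError(f"hands_on_hours must be non-negative, got {self.hands_on_hours}")
        if self.hands_on_hours > MAX_HOURS_PER_TRIAL * self.trials + _HOURS_TOL:
            raise ValueError(
                f"hands_on_hours {self.hands_on_hours} exceeds the 30-minute-per-trial "
                f"cap for {self.trials} trial(s)"
            )
        if self.billed_days <= 0 or not _on_half_day_grid(self.billed_days):
            raise ValueError(
                f"billed_days must be a positive multiple of 0.5 (half-day grid), "
                f"got {self.billed_days}"
            )
        if self.billed_days > MAX_BILLED_DAYS + _GRID_TOL:
            raise ValueError(
                f"billed_days {self.billed_days} exceeds the {MAX_BILLED_DAYS}-day training limit"
            )
        if not isinstance(self.nights, int) or self.nights < 0:
            raise ValueError(f"nights must be a non-negative integer, got {self.nights!r}")


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one curriculum group.

    ``mean_trials`` may be None when the trial count is not observed and the
    group is anchored on hands-on hours instead.
    """

    group: str
    n: int
    prop_proficient: float
    mean_trials: Optional[float]
    mean_hours: float
    mean_days: float
    median_days: float
    mean_nights: float

    def to_dict(self) -> dict:
        return asdict(self)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean proficiency flag")


def read_records(path: Union[str, Path], *, delimiter: str = ",") -> list[TraineeRecord]:
    """Read trainee records from a delimited text file.

    The file must be UTF-8 with a header row naming all of
    ``trainee_id, group, trials, hands_on_hours, billed_days, nights,
    proficient``.  Every row is validated against the record invariants;
    invalid rows are collected and reported together with their row numbers.

    Raises
    ------
    SchemaError
        if a required column is absent.
    RecordValidationError
        if any row fails validation (half-day grid, caps, types).
    """
    frame = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[TraineeRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_number = i + 2  # header is row 1
        try:
            records.append(
                TraineeRecord(
                    trainee_id=str(getattr(row, "trainee_id")),
                    group=str(getattr(row, "group")),
                    trials=int(getattr(row, "trials")),
                    hands_on_hours=float(getattr(row, "hands_on_hours")),
                    billed_days=float(getattr(row, "billed_days")),
                    nights=int(getattr(row, "nights")),
                    proficient=_parse_bool(getattr(row, "proficient")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((row_number, str(exc)))
    if errors:
        raise RecordValidationError(errors)
    return records


def to_frame(records: Iterable[TraineeRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the canonical column order."""
    return pd.DataFrame([asdict(r) for r in records], columns=list(COLUMNS))


def write_records(records: Iterable[TraineeRecord], path: Union[str, Path]) -> None:
    """Write records to CSV (UTF-8, header, lossless round-trip)."""
    to_frame(records).to_csv(path, index=False)


def group_counts(records: Iterable[TraineeRecord]) -> dict[str, int]:
    counts = {g: 0 for g in GROUPS}
    for r in records:
        counts[r.group] += 1
    return counts


def summarize_group(records: Iterable[TraineeRecord], group: str) -> GroupSummary:
    """Arithmetic means/medians of one group's records.

    ``prop_proficient`` is the exact fraction of proficient trainees.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    sub = [r for r in records if r.group == group]
    if not sub:
        raise EmptyGroupError(f"no records for group {group!r}")
    n = len(sub)
    return GroupSummary(
        group=group,
        n=n,
        prop_proficient=sum(r.proficient for r in sub) / n,
        mean_trials=sum(r.trials for r in sub) / n,
        mean_hours=sum(r.hands_on_hours for r in sub) / n,
        mean_days=sum(r.billed_days for r in sub) / n,
        median_days=float(statistics.median(r.billed_days for r in sub)),
        mean_nights=sum(r.nights for r in sub) / n,
    )


def summarize_all(records: Iterable[TraineeRecord]) -> dict[str, GroupSummary]:
    """Summaries for every group present in the records."""
    records = list(records)
    present = [g for g in GROUPS if any(r.group == g for r in records)]
    return {g: summarize_group(records, g) for g in present}


def percent_increase(reference: float, value: float) -> int:
    """Percent change of ``value`` relative to ``reference``, half-up integer.

    E.g. mean hands-on hours of 3.38 against a 2.96 reference is +14%.
    """
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    ref = Fraction(str(reference)) if isinstance(reference, float) else Fraction(reference)
    val = Fraction(str(value)) if isinstance(value, float) else Fraction(value)
    return round_half_up(100 * (val - ref) / ref)
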