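"""Training-cost arithmetic: variable costs, fixed-cost amortization, totals.

The cost structure distinguishes two components:

* a per-trainee **variable cost** v_g — laboratory days billed at a daily
  rate plus hotel nights at a nightly rate, both consumed until the trainee
  reaches proficiency (or exhausts the allocation);
* a one-time **fixed cost** for developing and validating the performance
  metrics and e-learning content, charged only to the metric-based curricula
  (G1–G3) and amortized evenly over the number of trainees.

All arithmetic is exact (integer cents; Fractions after division).  Display
rounding is half-up to whole euros and happens only at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Union

from .money import cents, eur, round_half_up
from .records import TraineeRecord

#: Calibration provenance of a group cost profile.
CALIBRATION_SOURCES = ("from_records", "from_printed_per_trainee_at_12")


@dataclass(frozen=True)
class CostRates:
    """Unit prices and the fixed metrics-development cost, in euro cents.

    Defaults are the source trial's actual rates: €2450 per person-day of
    laboratory time, €200 per hotel night, and €132 377 of one-time metrics
    development/validation cost.
    """

    lab_day_cents: int = 245000
    hotel_night_cents: int = 20000
    fixed_metrics_cents: int = 13237700

    def __post_init__(self) -> None:
        for name in ("lab_day_cents", "hotel_night_cents", "fixed_metrics_cents"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_euros(
        cls,
        lab_day: Union[int, float, str] = 2450,
        hotel_night: Union[int, float, str] = 200,
        fixed_metrics: Union[int, float, str] = 132377,
    ) -> "CostRates":
        return cls(cents(lab_day), cents(hotel_night), cents(fixed_metrics))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Union[int, float, str]]) -> "CostRates":
        """Build from a config mapping with euro-denominated keys."""
        return cls.from_euros(
            lab_day=mapping.get("lab_day_eur", 2450),
            hotel_night=mapping.get("hotel_night_eur", 200),
            fixed_metrics=mapping.get("fixed_metrics_eur", 132377),
        )

    def to_mapping(self) -> dict:
        return {
            "lab_day_eur": self.lab_day_cents / 100,
            "hotel_night_eur": self.hotel_night_cents / 100,
            "fixed_metrics_eur": self.fixed_metrics_cents / 100,
        }


@dataclass(frozen=True)
class GroupCostProfile:
    """A curriculum's calibrated per-trainee variable cost.

    ``carries_fixed_cost`` marks the metric-based curricula that share the
    fixed metrics cost; the apprenticeship curriculum does not.
    """

    group: str
    variable_cost_cents: int
    carries_fixed_cost: bool
    calibration_source: str

    def __post_init__(self) -> None:
        if self.variable_cost_cents <= 0:
            raise ValueError(f"variable cost must be positive, got {self.variable_cost_cents}")
        if self.calibration_source not in CALIBRATION_SOURCES:
            raise ValueError(
                f"calibration_source must be one of {CALIBRATION_SOURCES}, "
                f"got {self.calibration_source!r}"
            )


def amortize_fixed(fixed_cost_cents: int, n_trainees: int) -> Fraction:
    """Even per-trainee share of a fixed cost, exact (Fraction of cents).

    Display with :func:`pbpcost.money.eur`: 132 377 euros over 12 trainees
    shows as €11 031, over 500 as €265.
    """
    if n_trainees < 1:
        raise ValueError(f"n_trainees must be >= 1, got {n_trainees}")
    if fixed_cost_cents < 0:
        raise ValueError(f"fixed cost must be non-negative, got {fixed_cost_cents}")
    return Fraction(fixed_cost_cents, n_trainees)


def trainee_cost(record: TraineeRecord, rates: CostRates) -> int:
    """Variable cost of one trainee in cents: lab days + hotel nights.

    Exact because billed days sit on the half-day grid and the daily rate is
    an even number of cents.
    """
    half_days = round(record.billed_days * 2)
    lab = half_days * rates.lab_day_cents // 2
    if half_days * rates.lab_day_cents % 2:
        raise ValueError("lab day rate does not divide evenly over half days")
    return lab + record.nights * rates.hotel_night_cents


def per_trainee_cost(profile: GroupCostProfile, rates: CostRates, n_trainees: int) -> Fraction:
    """Exact per-trainee cost at cohort size n (cents).

    v_g plus the amortized fixed share for fixed-cost-bearing curricula;
    constant v_g otherwise.
    """
    if n_trainees < 1:
        raise ValueError(f"n_trainees must be >= 1, got {n_trainees}")
    base = Fraction(profile.variable_cost_cents)
    if profile.carries_fixed_cost:
        return base + amortize_fixed(rates.fixed_metrics_cents, n_trainees)
    return base


def total_cost(profile: GroupCostProfile, rates: CostRates, n_trainees: int) -> int:
    """Exact total cohort cost at size n (cents): affine, n·v_g + fixed.

    The fixed metrics cost is charged once, never re-charged as the cohort
    grows.
    """
    if n_trainees < 1:
        raise ValueError(f"n_trainees must be >= 1, got {n_trainees}")
    fixed = rates.fixed_metrics_cents if profile.carries_fixed_cost else 0
    return n_trainees * profile.variable_cost_cents + fixed


def cost_per_proficient_trainee(
    profile: GroupCostProfile,
    rates: CostRates,
    n_trainees: int,
    proficiency_rate: Union[float, Fraction],
) -> Fraction:
    """Effective cost per trainee who actually reaches the benchmark.

    Divides the per-trainee cost by the proficiency rate: money spent on
    trainees who never reach proficiency is attributed to those who do.  At a
    100% rate this is the ordinary per-trainee cost.
    """
    rate = Fraction(str(proficiency_rate)) if isinstance(proficiency_rate, float) else Fraction(proficiency_rate)
    if not 0 < rate <= 1:
        raise ValueError(f"proficiency_rate must be in (0, 1], got {proficiency_rate}")
    return per_trainee_cost(profile, rates, n_trainees) / rate


def profile_from_printed(
    group: str,
    per_trainee_at_12_eur: int,
    rates: CostRates,
    *,
    carries_fixed_cost: bool,
) -> GroupCostProfile:
    """Calibrate v_g from a published per-trainee cost at the 12-trainee anchor.

    For fixed-cost-bearing groups, v_g is the anchor minus the displayed
    (whole-euro) amortized share at 12 — the decomposition under which the
    published per-trainee figures at other cohort sizes reproduce exactly.
    """
    v_eur = per_trainee_at_12_eur
    if carries_fixed_cost:
        v_eur = per_trainee_at_12_eur - eur(amortize_fixed(rates.fixed_metrics_cents, 12))
    if v_eur <= 0:
        raise ValueError(
            f"anchor {per_trainee_at_12_eur} leaves non-positive variable cost for {group}"
        )
    return GroupCostProfile(
        group=group,
        variable_cost_cents=v_eur * 100,
        carries_fixed_cost=carries_fixed_cost,
        calibration_source="from_printed_per_trainee_at_12",
    )


def profile_from_records(
    records: Iterable[TraineeRecord],
    group: str,
    rates: CostRates,
    *,
    carries_fixed_cost: bool,
) -> GroupCostProfile:
    """Calibrate v_g as the mean observed variable cost of a group's records."""
    sub = [r for r in records if r.group == group]
    if not sub:
        raise ValueError(f"no records for group {group!r}")
    mean_cents = Fraction(sum(trainee_cost(r, rates) for r in sub), len(sub))
    return GroupCostProfile(
        group=group,
        variable_cost_cents=round_half_up(mean_cents),
        carries_fixed_cost=carries_fixed_cost,
        calibration_source="from_records",
    )
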