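"""Seeded synthetic cohort generator.

No trainee-level dataset is deposited for the underlying randomized trial,
only group-level statistics.  This module generates cohorts whose structure
matches those statistics so that every downstream stage — costing, scaling
projection, resampling — is exercisable and testable from a seed alone.

Model
-----
Training is a sequence of 30-minute console trials.  Under the Markov view of
progression, each trial meets the proficiency benchmark with a fixed
per-trial probability ``p``, independent of history, so trials-to-proficiency
is geometric(first success), censored at a maximum trial count implied by the
3.5-day laboratory limit.  Hands-on hours are exactly 0.5 h per trial.
Billable laboratory days are drawn from a calibrated distribution on the
half-day grid {0.5, 1.0, ..., 3.5}; hotel nights follow the policy
``nights = max(1, round_half_up(billed_days))``.  Trainees who never reach
the benchmark (apprenticeship arm only, in the source trial) consume the full
allocation: trials at the cap and the maximum billable days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .records import GroupSummary, TraineeRecord

HALF_DAY_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)

#: Default trial cap under the 3.5-day limit (~7 slots/day over 3.5 days,
#: rounded to a round ceiling that no observed group mean approaches).
DEFAULT_MAX_TRIALS = 30


class CalibrationError(ValueError):
    """The calibration target is unreachable under the stated caps."""


def censored_geometric_mean(p: float, cap: int) -> float:
    """E[min(T, cap)] for T ~ geometric(p) on {1, 2, ...}.

    Closed form: sum_{k=0}^{cap-1} (1-p)^k = (1 - (1-p)^cap) / p.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if p == 1:
        return 1.0
    return (1.0 - (1.0 - p) ** cap) / p


def solve_success_probability(mean_trials: float, cap: int) -> float:
    """Invert the censored-geometric mean: find p with E[min(T, cap)] = target.

    The censored mean decreases monotonically from ``cap`` (p -> 0) to 1
    (p = 1), so the root is unique; solved by bracketing.
    """
    if not 1 <= mean_trials <= cap:
        raise CalibrationError(
            f"target mean of {mean_trials} trials is unreachable with a cap of {cap}"
        )
    if mean_trials == 1:
        return 1.0
    return float(brentq(lambda p: censored_geometric_mean(p, cap) - mean_trials, 1e-12, 1.0))


def halfday_weights(mean_days: float, grid: Sequence[float] = HALF_DAY_GRID) -> tuple[float, ...]:
    """Probability weights on the half-day grid with the exact target mean.

    Uses the minimal-support solution: all mass on the two grid points
    bracketing the target (one point if the target sits on the grid).
    """
    grid = tuple(grid)
    if not grid[0] <= mean_days <= grid[-1]:
        raise CalibrationError(
            f"target mean of {mean_days} days lies outside the grid [{grid[0]}, {grid[-1]}]"
        )
    weights = [0.0] * len(grid)
    for i in range(len(grid) - 1):
        lo, hi = grid[i], grid[i + 1]
        if lo <= mean_days <= hi:
            w = (hi - mean_days) / (hi - lo)
            weights[i] = w
            weights[i + 1] = 1.0 - w
            return tuple(weights)
    weights[-1] = 1.0
    return tuple(weights)


@dataclass(frozen=True)
class GroupGeneratorParams:
    """Generator parameters for one curriculum group.

    ``p_success_per_trial`` drives the censored-geometric trials distribution
    for trainees who reach the benchmark; ``day_weights`` is the calibrated
    distribution of their billable days; ``proficiency_rate`` is the target
    fraction reaching the benchmark (1.0 for the PBP-derived groups, 7/12 for
    the apprenticeship arm); non-proficient trainees get the full allocation
    (``max_trials`` trials, ``nonproficient_days`` billable days).
    """

    group: str
    p_success_per_trial: float
    day_weights: tuple[float, ...]
    day_grid: tuple[float, ...] = HALF_DAY_GRID
    max_trials: int = DEFAULT_MAX_TRIALS
    minutes_per_trial: float = 30.0
    proficiency_rate: float = 1.0
    nonproficient_days: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.p_success_per_trial <= 1:
            raise ValueError(f"p_success_per_trial must be in (0, 1], got {self.p_success_per_trial}")
        if not 0 < self.proficiency_rate <= 1:
            raise ValueError(f"proficiency_rate must be in (0, 1], got {self.proficiency_rate}")
        if len(self.day_weights) != len(self.day_grid):
            raise ValueError("day_weights and day_grid must have equal length")
        if abs(sum(self.day_weights) - 1.0) > 1e-9:
            raise ValueError(f"day_weights must sum to 1, got {sum(self.day_weights)}")
        if any(w < 0 for w in self.day_weights):
            raise ValueError("day_weights must be non-negative")
        if self.max_trials < 1:
            raise ValueError(f"max_trials must be >= 1, got {self.max_trials}")


def calibrate_params(
    target: GroupSummary,
    *,
    max_trials: int = DEFAULT_MAX_TRIALS,
    minutes_per_trial: float = 30.0,
    nonproficient_days: float = 3.5,
) -> GroupGeneratorParams:
    """Solve generator parameters so the cohort reproduces a target summary.

    The cohort mean is a mixture over proficient (rate ``r``) and
    non-proficient (``1 - r``, pinned at the caps) trainees, so the solver
    inverts the mixture:

        r * E[min(Geom(p), cap)] + (1 - r) * cap            = mean_trials
        r * E[days | proficient] + (1 - r) * nonprof_days   = mean_days

    which reduces to a plain censored-geometric mean inversion when r = 1.
    Groups without an observed trial count are anchored on mean hands-on
    hours via the 0.5 h/trial link.
    """
    r = target.prop_proficient
    if not 0 < r <= 1:
        raise CalibrationError(f"proficiency rate must be in (0, 1], got {r}")

    mean_trials = target.mean_trials
    if mean_trials is None:
        mean_trials = target.mean_hours / (minutes_per_trial / 60.0)

    prof_mean_trials = (mean_trials - (1 - r) * max_trials) / r
    if not 1 <= prof_mean_trials <= max_trials:
        raise CalibrationError(
            f"mean of {mean_trials} trials at proficiency rate {r} implies "
            f"{prof_mean_trials:.2f} trials among proficient trainees, outside [1, {max_trials}]"
        )
    p = solve_success_probability(prof_mean_trials, max_trials)

    prof_mean_days = (target.mean_days - (1 - r) * nonproficient_days) / r
    weights = halfday_weights(prof_mean_days)

    return GroupGeneratorParams(
        group=target.group,
        p_success_per_trial=p,
        day_weights=weights,
        max_trials=max_trials,
        minutes_per_trial=minutes_per_trial,
        proficiency_rate=r,
        nonproficient_days=nonproficient_days,
    )


def generate_cohort(params: GroupGeneratorParams, n: int, seed: int) -> list[TraineeRecord]:
    """Generate ``n`` trainee records; deterministic given (params, n, seed)."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")

    rng = np.random.default_rng(int(seed))
    proficient = rng.random(n) < params.proficiency_rate
    trials = np.minimum(rng.geometric(params.p_success_per_trial, size=n), params.max_trials)
    days = rng.choice(np.asarray(params.day_grid), size=n, p=np.asarray(params.day_weights))

    trials = np.where(proficient, trials, params.max_trials).astype(int)
    days = np.where(proficient, days, params.nonproficient_days)
    nights = np.maximum(1, np.floor(days + 0.5).astype(int))
    hours = trials * (params.minutes_per_trial / 60.0)

    return [
        TraineeRecord(
            trainee_id=f"{params.group}-s{int(seed)}-{i:05d}",
            group=params.group,
            trials=int(trials[i]),
            hands_on_hours=float(hours[i]),
            billed_days=float(days[i]),
            nights=int(nights[i]),
            proficient=bool(proficient[i]),
        )
        for i in range(n)
    ]
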