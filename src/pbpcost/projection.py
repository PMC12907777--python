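"""Cohort-scaling projections, cost-equivalence points, relative costs.

The scaling question: a metric-based curriculum pays a one-time fixed cost F
but trains each trainee more cheaply (variable cost v_a), while the
apprenticeship alternative has no fixed cost but a higher per-trainee cost
v_b.  Per-trainee cost of the former falls as v_a + F/N; the curricula's
total costs cross at the cost-equivalence point N* = F / (v_b - v_a), beyond
which the fixed-cost-bearing curriculum is cheaper.

The trials-to-proficiency process behind the variable costs is an absorbing
Markov chain: from each transient state (trial count so far) the trainee
absorbs into "proficient" with probability p or continues with 1 - p, giving
a censored-geometric time to absorption (:class:`ProgressionModel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .costs import CostRates, GroupCostProfile, amortize_fixed, per_trainee_cost, total_cost
from .money import eur, round_half_up
from .synthetic import censored_geometric_mean
from .uncertainty import IntervalEstimate


@dataclass(frozen=True)
class ProgressionModel:
    """Absorbing-chain training-progression model for one curriculum.

    State space: trial counts 0..max_trials plus an absorbing proficient
    state; every trial absorbs with probability ``p_success_per_trial`` and
    continues otherwise, so transition mass out of each transient state sums
    to one by construction.  Censoring at ``max_trials`` encodes the finite
    laboratory allocation.
    """

    group: str
    p_success_per_trial: float
    max_trials: int

    def __post_init__(self) -> None:
        if not 0 < self.p_success_per_trial <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p_success_per_trial}")
        if self.max_trials < 1:
            raise ValueError(f"max_trials must be >= 1, got {self.max_trials}")

    def expected_trials(self) -> float:
        """Expected trials to absorption, censored at the cap (closed form)."""
        return censored_geometric_mean(self.p_success_per_trial, self.max_trials)

    def trial_pmf(self) -> np.ndarray:
        """P(min(T, cap) = k) for k = 1..cap; censored mass pools at the cap."""
        p, cap = self.p_success_per_trial, self.max_trials
        k = np.arange(1, cap + 1)
        pmf = (1 - p) ** (k - 1) * p
        pmf[-1] = (1 - p) ** (cap - 1)  # reach the cap: succeed there or censor
        return pmf

    def simulate(self, n: int, seed: int) -> np.ndarray:
        """Monte-Carlo trials-to-absorption for n independent trainees."""
        rng = np.random.default_rng(seed)
        return np.minimum(rng.geometric(self.p_success_per_trial, size=n), self.max_trials)


def expected_trials(model: ProgressionModel) -> float:
    """Module-level convenience alias for ``model.expected_trials()``."""
    return model.expected_trials()


@dataclass(frozen=True)
class EquivalenceResult:
    """Cost-equivalence between a fixed-cost-bearing and a flat curriculum.

    ``n_star`` is the real-valued cohort size where total costs are equal;
    ``break_even_cohort`` the smallest integer cohort at which the
    fixed-cost-bearing curriculum is strictly cheaper.  ``crosses`` is False
    when the flat curriculum is never more expensive (no crossing).
    """

    crosses: bool
    n_star: Optional[float] = None
    break_even_cohort: Optional[int] = None


def equivalence_point(
    profile_fixed: GroupCostProfile,
    profile_flat: GroupCostProfile,
    rates: CostRates,
) -> EquivalenceResult:
    """Solve v_a + F/N = v_b for the cohort size N* where costs are equal.

    Closed form on the linear cost model: N* = F / (v_b - v_a).  Returns an
    explicit no-crossing result (not an exception) when v_b <= v_a.
    """
    if not profile_fixed.carries_fixed_cost:
        raise ValueError("profile_fixed must carry the fixed cost")
    if profile_flat.carries_fixed_cost:
        raise ValueError("profile_flat must not carry the fixed cost")
    va = Fraction(profile_fixed.variable_cost_cents)
    vb = Fraction(profile_flat.variable_cost_cents)
    if vb <= va:
        return EquivalenceResult(crosses=False)
    n_star = Fraction(rates.fixed_metrics_cents) / (vb - va)
    # smallest integer N with strictly lower total for the fixed-cost curve
    break_even = math.floor(n_star) + 1
    return EquivalenceResult(crosses=True, n_star=float(n_star), break_even_cohort=break_even)


def relative_cost_advantage(cost_ref: float, cost_alt: float) -> int:
    """How much more expensive the reference is than the alternative, in %.

    100 * (cost_ref - cost_alt) / cost_alt, rounded half-up to an integer:
    e.g. 7 067 vs 3 373 per trainee is a 110% advantage for the alternative.
    """
    if cost_alt <= 0:
        raise ValueError(f"cost_alt must be positive, got {cost_alt}")
    ref = Fraction(str(cost_ref)) if isinstance(cost_ref, float) else Fraction(cost_ref)
    alt = Fraction(str(cost_alt)) if isinstance(cost_alt, float) else Fraction(cost_alt)
    return round_half_up(100 * (ref - alt) / alt)


@dataclass(frozen=True)
class ProjectionGrid:
    """Per-trainee and total costs across cohort sizes, one row per
    (cohort size, group).

    ``total_eur`` is cohort size x the display-rounded per-trainee cost (the
    reporting convention of the source analysis, and the form in which the
    grid invariant total = size x per-trainee holds exactly);
    ``total_exact_eur`` is the exactly affine n·v_g + F.  The two differ by
    at most half a euro per trainee.
    """

    table: pd.DataFrame
    sizes: tuple[int, ...]
    groups: tuple[str, ...]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def project(
    profiles: Mapping[str, GroupCostProfile],
    rates: CostRates,
    sizes: Sequence[int],
    intervals: Optional[Mapping[str, IntervalEstimate]] = None,
) -> ProjectionGrid:
    """Populate the cost grid over cohort sizes for every group profile.

    ``intervals``, when given, are uncertainty intervals on each group's
    per-trainee *variable* cost (euros); the fixed amortized share is a known
    constant, so per-trainee bounds shift by it and total bounds scale by
    cohort size.
    """
    sizes = tuple(int(s) for s in sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(s < 1 for s in sizes):
        raise ValueError(f"cohort sizes must be positive, got {sizes}")

    rows = []
    groups = tuple(profiles)
    for n in sizes:
        for g in groups:
            prof = profiles[g]
            share = amortize_fixed(rates.fixed_metrics_cents, n) if prof.carries_fixed_cost else 0
            pt = eur(per_trainee_cost(prof, rates, n))
            row = {
                "cohort_size": n,
                "group": g,
                "amortized_fixed_eur": eur(share),
                "per_trainee_eur": pt,
                "total_eur": n * pt,
                "total_exact_eur": eur(total_cost(prof, rates, n)),
            }
            if intervals is not None and g in intervals:
                ci = intervals[g]
                share_eur = float(Fraction(share) / 100)
                row["per_trainee_lo_eur"] = round_half_up(ci.lo + share_eur)
                row["per_trainee_hi_eur"] = round_half_up(ci.hi + share_eur)
                row["total_lo_eur"] = round_half_up(n * (ci.lo + share_eur))
                row["total_hi_eur"] = round_half_up(n * (ci.hi + share_eur))
            rows.append(row)
    return ProjectionGrid(table=pd.DataFrame(rows), sizes=sizes, groups=groups)
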