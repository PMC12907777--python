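"""Resampling-based uncertainty for cost estimates.

Confidence intervals for the mean per-trainee variable cost come from the
percentile bootstrap (a normal-theory interval is available as a
cross-check); the fixed amortized share is a known constant and contributes
no width.  Between-group differences in mean cost are tested with a
two-sided permutation test, with exact enumeration available for small
groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

_EPS = 1e-12


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with an uncertainty interval.

    ``degenerate`` flags intervals collapsed to zero width because the input
    had no variation (returned, not raised).
    """

    point: float
    lo: float
    hi: float
    level: float = 0.95
    method: str = "percentile_bootstrap"
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not self.lo - _EPS <= self.point <= self.hi + _EPS:
            raise ValueError(
                f"interval [{self.lo}, {self.hi}] does not contain the point {self.point}"
            )

    @property
    def half_width(self) -> float:
        return (self.hi - self.lo) / 2

    def scaled(self, factor: float) -> "IntervalEstimate":
        """Interval for ``factor`` x the estimand (e.g. total = N x per-trainee)."""
        if factor < 0:
            raise ValueError("factor must be non-negative")
        return replace(self, point=factor * self.point, lo=factor * self.lo, hi=factor * self.hi)

    def shifted(self, offset: float) -> "IntervalEstimate":
        """Interval for the estimand plus a known constant (zero variance)."""
        return replace(self, point=self.point + offset, lo=self.lo + offset, hi=self.hi + offset)


def bootstrap_ci(
    values: Sequence[float],
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> IntervalEstimate:
    """Percentile-bootstrap interval for the mean; deterministic given seed.

    Constant input yields a degenerate zero-width interval (flagged).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if n_boot < 1000:
        raise ValueError(f"n_boot must be >= 1000, got {n_boot}")
    point = float(x.mean())
    if np.ptp(x) == 0:
        return IntervalEstimate(point, point, point, level, "percentile_bootstrap",
                                n_boot, seed, degenerate=True)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return IntervalEstimate(point, float(lo), float(hi), level,
                            "percentile_bootstrap", n_boot, seed)


def normal_ci(values: Sequence[float], level: float = 0.95) -> IntervalEstimate:
    """Normal-theory (z) interval for the mean — cross-check for the bootstrap."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    point = float(x.mean())
    se = float(x.std(ddof=1)) / math.sqrt(x.size)
    if se == 0:
        return IntervalEstimate(point, point, point, level, "normal", degenerate=True)
    z = float(stats.norm.ppf(0.5 + level / 2))
    return IntervalEstimate(point, point - z * se, point + z * se, level, "normal")


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 9_999,
    seed: Optional[int] = None,
) -> float:
    """Two-sided Monte-Carlo permutation p-value for a difference in means.

    Uses the add-one correction p = (b + 1) / (n_perm + 1), so the smallest
    attainable p is 1 / (n_perm + 1).  Deterministic given seed.  Returns
    exactly 1 when the pooled values are all identical.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 999:
        raise ValueError(f"n_perm must be >= 999, got {n_perm}")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, pooled.size)).copy(), axis=1)
    diffs = perms[:, : a.size].mean(axis=1) - perms[:, a.size :].mean(axis=1)
    extreme = int(np.sum(np.abs(diffs) >= observed - _EPS))
    return (extreme + 1) / (n_perm + 1)


def exact_permutation_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Exact two-sided permutation p-value by full enumeration.

    Enumerates every partition of the pooled values into groups of the
    observed sizes; feasible for small groups (C(12, 6) = 924 partitions for
    6 + 6).  The identity partition is always counted, so p >= 1/C(n, n_a).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    n = pooled.size
    total = pooled.sum()
    count = 0
    n_part = 0
    for idx in combinations(range(n), a.size):
        sa = pooled[list(idx)].sum()
        diff = abs(sa / a.size - (total - sa) / b.size)
        count += diff >= observed - _EPS
        n_part += 1
    return count / n_part
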