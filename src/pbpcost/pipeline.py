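"""End-to-end reproduction pipeline: one config in, one report bundle out.

``run_reproduction`` ties the stages together: generate calibrated synthetic
cohorts, summarize learning performance, calibrate cost profiles, project
per-trainee and total costs across cohort sizes with bootstrap intervals,
locate the cost-equivalence point, and run between-group permutation tests.
All outputs are plain CSV/JSON tables written atomically (staged in a
temporary directory, then renamed), and two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import osset
from .costs import CostRates, profile_from_records, trainee_cost, cost_per_proficient_trainee
from .money import eur
from .projection import equivalence_point, project, relative_cost_advantage
from .records import GROUPS, percent_increase, summarize_all, to_frame
from .synthetic import generate_cohort
from .uncertainty import bootstrap_ci, permutation_test

logger = logging.getLogger(__name__)

DEFAULT_SEED = 1729


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproduction run depends on, serializable next to its outputs."""

    rates: CostRates = field(default_factory=CostRates)
    calibration_source: str = "from_printed"  # or "from_records"
    sizes: tuple[int, ...] = osset.SIZE_GRID
    cohort_n: int = osset.COHORT_N
    seed: int = DEFAULT_SEED
    n_boot: int = 10_000
    n_perm: int = 9_999
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.calibration_source not in ("from_printed", "from_records"):
            raise ValueError(f"unknown calibration_source {self.calibration_source!r}")
        if self.cohort_n < 1 or not self.sizes:
            raise ValueError("cohort_n must be >= 1 and sizes non-empty")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "rates" in raw:
            kwargs["rates"] = CostRates.from_mapping(raw["rates"])
        for key in ("calibration_source", "cohort_n", "seed", "n_boot", "n_perm", "level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "sizes" in raw:
            kwargs["sizes"] = tuple(int(s) for s in raw["sizes"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rates"] = self.rates.to_mapping()
        d["sizes"] = list(self.sizes)
        return d


def group_seed(base_seed: int, group: str) -> int:
    """Derived per-group stream seed (stable, below 2**31)."""
    return (base_seed * 10 + GROUPS.index(group)) % (2**31 - 1)


def run_reproduction(config: RunConfig, outdir: Union[str, Path]) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle into ``outdir``.

    Returns a mapping from artifact name to written path.  Outputs are
    staged and renamed so a failure part-way leaves no half-written tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rates = config.rates

    # --- synthetic cohorts under the study conditions -----------------------
    params = osset.generator_params()
    cohorts = {
        g: generate_cohort(params[g], config.cohort_n, group_seed(config.seed, g))
        for g in GROUPS
    }
    all_records = [r for g in GROUPS for r in cohorts[g]]
    logger.info("generated %d synthetic trainees in %d groups (seed=%d)",
                len(all_records), len(GROUPS), config.seed)

    # --- learning summaries (observed for the cohorts, plus printed anchors)
    observed = summarize_all(all_records)
    ref_hours = osset.PRINTED_SUMMARIES["G1_full_pbp"].mean_hours
    summary_rows = []
    for g in GROUPS:
        anchor, obs = osset.PRINTED_SUMMARIES[g], observed[g]
        summary_rows.append({
            "group": g,
            "n": obs.n,
            "prop_proficient": round(obs.prop_proficient, 4),
            "mean_trials": round(obs.mean_trials, 3),
            "mean_hours": round(obs.mean_hours, 3),
            "mean_days": round(obs.mean_days, 3),
            "median_days": obs.median_days,
            "mean_nights": round(obs.mean_nights, 3),
            "anchor_mean_hours": anchor.mean_hours,
            "anchor_hours_increase_pct": percent_increase(ref_hours, anchor.mean_hours),
        })
    summaries_frame = pd.DataFrame(summary_rows)

    # --- cost profiles ------------------------------------------------------
    if config.calibration_source == "from_printed":
        profiles = osset.printed_profiles(rates)
    else:
        profiles = {
            g: profile_from_records(cohorts[g], g, rates,
                                    carries_fixed_cost=osset.CARRIES_FIXED_COST[g])
            for g in GROUPS
        }
    for g, prof in profiles.items():
        logger.info("profile %s: variable cost %.2f EUR, fixed=%s (%s)",
                    g, prof.variable_cost_cents / 100, prof.carries_fixed_cost,
                    prof.calibration_source)

    # --- bootstrap intervals on per-trainee variable cost -------------------
    intervals = {}
    for g in GROUPS:
        values = [trainee_cost(r, rates) / 100 for r in cohorts[g]]
        ci = bootstrap_ci(values, level=config.level, n_boot=config.n_boot,
                          seed=group_seed(config.seed + 1, g))
        intervals[g] = ci
        logger.info("bootstrap CI %s: %.0f [%.0f, %.0f] EUR", g, ci.point, ci.lo, ci.hi)

    # --- projection grid ----------------------------------------------------
    grid = project(profiles, rates, config.sizes, intervals=intervals)
    amort_frame = pd.DataFrame({
        "n_trainees": list(config.sizes),
        "amortized_per_trainee_eur": [
            eur(Fraction(rates.fixed_metrics_cents, n)) for n in config.sizes
        ],
    })

    # --- equivalence and relative-cost report -------------------------------
    g1, g4 = profiles["G1_full_pbp"], profiles["G4_apprenticeship"]
    equiv = equivalence_point(g1, g4, rates)
    pt = grid.table.set_index(["cohort_size", "group"])["per_trainee_eur"]
    advantages = {
        str(n): relative_cost_advantage(
            pt[(n, "G4_apprenticeship")], pt[(n, "G1_full_pbp")]
        )
        for n in config.sizes
    }
    g4_rate = osset.PRINTED_SUMMARIES["G4_apprenticeship"].prop_proficient
    equiv_report = {
        "equivalence_point_trainees": equiv.n_star,
        "break_even_cohort": equiv.break_even_cohort,
        "crosses": equiv.crosses,
        "g4_vs_g1_per_trainee_advantage_pct": advantages,
        "g4_cost_per_proficient_trainee_eur": eur(
            cost_per_proficient_trainee(g4, rates, osset.COHORT_N, Fraction(7, 12))
        ),
        "g4_proficiency_rate": round(g4_rate, 4),
    }
    logger.info("equivalence point: %.2f trainees (break-even cohort %s)",
                equiv.n_star or float("nan"), equiv.break_even_cohort)

    # --- permutation tests: G1 vs each other group --------------------------
    base_costs = [trainee_cost(r, rates) / 100 for r in cohorts["G1_full_pbp"]]
    perm_report = {}
    for g in GROUPS[1:]:
        other = [trainee_cost(r, rates) / 100 for r in cohorts[g]]
        p = permutation_test(base_costs, other, n_perm=config.n_perm,
                             seed=group_seed(config.seed + 2, g))
        perm_report[g] = p
        logger.info("permutation test G1 vs %s: p = %.4g", g, p)

    # --- atomic write of the bundle -----------------------------------------
    artifacts = {
        "cohorts.csv": lambda p: to_frame(all_records).to_csv(p, index=False),
        "group_summaries.csv": lambda p: summaries_frame.to_csv(p, index=False),
        "amortization_schedule.csv": lambda p: amort_frame.to_csv(p, index=False),
        "projection_grid.csv": lambda p: grid.to_csv(p),
        "equivalence.json": lambda p: Path(p).write_text(
            json.dumps(equiv_report, indent=2, sort_keys=True) + "\n", encoding="utf-8"),
        "permutation_tests.json": lambda p: Path(p).write_text(
            json.dumps(perm_report, indent=2, sort_keys=True) + "\n", encoding="utf-8"),
        "run_config.json": lambda p: Path(p).write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"),
    }
    written: dict[str, Path] = {}
    with tempfile.TemporaryDirectory(dir=outdir) as staging:
        staged = []
        for name, writer in artifacts.items():
            tmp = Path(staging) / name
            writer(tmp)
            staged.append((tmp, outdir / name))
        for tmp, final in staged:
            os.replace(tmp, final)
            written[final.name] = final
    return written
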