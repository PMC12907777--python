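"""Published study conditions of the source randomized trial (OSSET).

Four groups of 12 medical trainees each learned a robotic bladder-urethra
anastomosis under curricula with decreasing adherence to proficiency-based
progression.  No trainee-level data are deposited; the published group-level
statistics below are the calibration anchors for the whole analysis:

* learning outcomes per group (mean trials, hands-on hours, lab days,
  proficiency rate) calibrate the synthetic cohort generator;
* per-trainee costs at the 12-trainee anchor calibrate the group cost
  profiles used for scaling projections.

Notes on the anchors:

* Group 2's mean trial count was never published; it is derived from the
  published mean hands-on hours via the 0.5 h/trial link (3.38 h -> 6.76).
* Group 3 finished with 11 participants after one withdrawal; cost figures
  were nevertheless published for nominal 12-trainee cohorts, so the cost
  anchors here use n = 12 while observed-data summaries keep n = 11.
* Group 4's published 58% proficiency is the exact trial fraction 7/12.
* Mean hotel nights were published only for Groups 1 (1 night) and 4
  (3 nights); the Group 2/3 anchors apply the nights policy
  max(1, round_half_up(mean days)) used throughout.
* Group 2/3 per-trainee costs at 12 derive from their published group totals
  divided by 12 (174 144/12 = 14 512; 182 604/12 = 15 217).
"""

from __future__ import annotations

from .costs import CostRates, GroupCostProfile, profile_from_printed
from .records import GROUPS, GroupSummary
from .synthetic import GroupGeneratorParams, calibrate_params

#: Cohort sizes over which the published analysis projected costs.
SIZE_GRID = (12, 50, 100, 200, 300, 400, 500)

#: Nominal per-group cohort size used for all cost anchors.
COHORT_N = 12

#: Published group-level learning statistics (the generator's calibration
#: targets).  mean_trials None => anchored on hours (Group 2).
PRINTED_SUMMARIES: dict[str, GroupSummary] = {
    "G1_full_pbp": GroupSummary(
        group="G1_full_pbp", n=12, prop_proficient=1.0,
        mean_trials=5.92, mean_hours=2.96, mean_days=1.17,
        median_days=1.0, mean_nights=1.0,
    ),
    "G2_elearning": GroupSummary(
        group="G2_elearning", n=12, prop_proficient=1.0,
        mean_trials=None, mean_hours=3.38, mean_days=1.29,
        median_days=1.25, mean_nights=1.0,
    ),
    "G3_traditional": GroupSummary(
        group="G3_traditional", n=11, prop_proficient=1.0,
        mean_trials=12.0, mean_hours=6.00, mean_days=1.5,
        median_days=1.5, mean_nights=2.0,
    ),
    "G4_apprenticeship": GroupSummary(
        group="G4_apprenticeship", n=12, prop_proficient=7 / 12,
        mean_trials=15.0, mean_hours=7.75, mean_days=2.67,
        median_days=2.5, mean_nights=3.0,
    ),
}

#: Published per-trainee cost at the 12-trainee anchor (euros).
PRINTED_PER_TRAINEE_AT_12 = {
    "G1_full_pbp": 14139,
    "G2_elearning": 14512,
    "G3_traditional": 15217,
    "G4_apprenticeship": 7067,
}

#: Which curricula share the fixed metrics-development cost.
CARRIES_FIXED_COST = {
    "G1_full_pbp": True,
    "G2_elearning": True,
    "G3_traditional": True,
    "G4_apprenticeship": False,
}

DEFAULT_RATES = CostRates()


def printed_profiles(rates: CostRates = DEFAULT_RATES) -> dict[str, GroupCostProfile]:
    """Group cost profiles calibrated from the published 12-trainee anchors."""
    return {
        g: profile_from_printed(
            g, PRINTED_PER_TRAINEE_AT_12[g], rates, carries_fixed_cost=CARRIES_FIXED_COST[g]
        )
        for g in GROUPS
    }


def generator_params(**overrides) -> dict[str, GroupGeneratorParams]:
    """Per-group generator parameters calibrated to the published summaries."""
    return {g: calibrate_params(PRINTED_SUMMARIES[g], **overrides) for g in GROUPS}
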