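"""Cost arithmetic: amortization, variable costs, totals, exactness."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbpcost.costs import (
    CostRates,
    GroupCostProfile,
    amortize_fixed,
    cost_per_proficient_trainee,
    per_trainee_cost,
    profile_from_printed,
    profile_from_records,
    total_cost,
    trainee_cost,
)
from pbpcost.money import cents, eur, round_half_up
from pbpcost.records import TraineeRecord


class TestMoney:
    @pytest.mark.parametrize(
        "x, expected", [(0.5, 1), (1.49, 1), (1.5, 2), (-0.5, 0), (Fraction(5, 2), 3)]
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_cents_rejects_subcent_amounts(self):
        with pytest.raises(ValueError):
            cents(1.005)


class TestAmortization:
    @pytest.mark.parametrize(
        "n, expected_eur",
        [(12, 11031), (50, 2648), (100, 1324), (200, 662), (500, 265)],
    )
    def test_published_schedule(self, n, expected_eur):
        assert eur(amortize_fixed(cents(132377), n)) == expected_eur

    def test_zero_fixed_cost(self):
        assert amortize_fixed(0, 7) == 0

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            amortize_fixed(cents(132377), 0)

    @given(n=st.integers(min_value=1, max_value=10_000))
    def test_strictly_decreasing_in_cohort_size(self, n):
        fixed = cents(132377)
        assert amortize_fixed(fixed, n) > amortize_fixed(fixed, n + 1)

    def test_exact_internally_rounded_only_at_display(self):
        share = amortize_fixed(cents(132377), 12)
        assert share == Fraction(13237700, 12)  # not a whole cent
        assert eur(share) == 11031


class TestTraineeCost:
    @pytest.mark.parametrize(
        "days, nights, expected_eur",
        [(1.0, 1, 2650), (0.5, 0, 1225), (2.5, 3, 6725)],
    )
    def test_variable_cost_arithmetic(self, rates, days, nights, expected_eur):
        rec = TraineeRecord("t", "G1_full_pbp", 30, 15.0, days, nights, True)
        assert trainee_cost(rec, rates) == expected_eur * 100


class TestPerTraineeAndTotal:
    def test_published_per_trainee_trajectory(self, rates, profiles):
        g1 = profiles["G1_full_pbp"]
        assert g1.variable_cost_cents == 3108 * 100  # 14 139 − 11 031
        assert eur(per_trainee_cost(g1, rates, 12)) == 14139
        assert eur(per_trainee_cost(g1, rates, 50)) == 5756
        assert eur(per_trainee_cost(g1, rates, 500)) == 3373

    def test_flat_profile_constant_in_n(self, rates, profiles):
        g4 = profiles["G4_apprenticeship"]
        assert not g4.carries_fixed_cost
        assert {eur(per_trainee_cost(g4, rates, n)) for n in (1, 12, 50, 500)} == {7067}

    def test_total_cost_affine_and_linear_increment(self, rates, profiles):
        for prof in profiles.values():
            fixed = rates.fixed_metrics_cents if prof.carries_fixed_cost else 0
            for n in (1, 12, 50, 499):
                assert total_cost(prof, rates, n) == n * prof.variable_cost_cents + fixed
                # growing the cohort never re-charges the fixed cost
                assert (
                    total_cost(prof, rates, n + 12) - total_cost(prof, rates, n)
                    == 12 * prof.variable_cost_cents
                )

    def test_per_trainee_converges_to_variable_cost(self, rates, profiles):
        g1 = profiles["G1_full_pbp"]
        at_limit = per_trainee_cost(g1, rates, 10**9)
        assert at_limit - g1.variable_cost_cents < 1  # within one cent

    def test_per_trainee_strictly_decreasing_for_fixed_cost_groups(self, rates, profiles):
        g1 = profiles["G1_full_pbp"]
        values = [per_trainee_cost(g1, rates, n) for n in range(1, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_total_matches_brute_force_record_summation(self, rates, gen_params):
        """Affine total equals summing per-record costs plus the fixed charge,
        up to the cent rounding of the calibrated mean."""
        from pbpcost.synthetic import generate_cohort

        cohort = generate_cohort(gen_params["G1_full_pbp"], 60, seed=3)
        prof = profile_from_records(cohort, "G1_full_pbp", rates, carries_fixed_cost=True)
        brute = sum(trainee_cost(r, rates) for r in cohort) + rates.fixed_metrics_cents
        assert abs(total_cost(prof, rates, 60) - brute) <= 60 / 2  # <= half-cent each


class TestCostPerProficientTrainee:
    def test_identity_at_full_proficiency(self, rates, profiles):
        g4 = profiles["G4_apprenticeship"]
        assert eur(cost_per_proficient_trainee(g4, rates, 12, 1.0)) == 7067
        g1 = profiles["G1_full_pbp"]
        assert eur(cost_per_proficient_trainee(g1, rates, 500, 1.0)) == 3373

    def test_apprenticeship_effective_cost(self, rates, profiles):
        g4 = profiles["G4_apprenticeship"]
        # 7 067 × 12/7: spending attributed to the 7 of 12 who reached benchmark
        assert eur(cost_per_proficient_trainee(g4, rates, 12, Fraction(7, 12))) == 12115

    def test_zero_rate_rejected(self, rates, profiles):
        with pytest.raises(ValueError):
            cost_per_proficient_trainee(profiles["G4_apprenticeship"], rates, 12, 0.0)


class TestProfiles:
    def test_printed_calibration_decomposition(self, rates):
        # G2/G3 anchors are published group totals over 12
        for group, anchor, expected_v in [
            ("G2_elearning", 174144 // 12, 3481),
            ("G3_traditional", 182604 // 12, 4186),
        ]:
            prof = profile_from_printed(group, anchor, rates, carries_fixed_cost=True)
            assert prof.variable_cost_cents == expected_v * 100

    def test_record_calibration_averages_observed_costs(self, rates):
        recs = [
            TraineeRecord("a", "G1_full_pbp", 2, 1.0, 1.0, 1, True),   # 2 650
            TraineeRecord("b", "G1_full_pbp", 4, 2.0, 1.5, 2, True),   # 4 075
        ]
        prof = profile_from_records(recs, "G1_full_pbp", rates, carries_fixed_cost=True)
        assert prof.variable_cost_cents == round_half_up(Fraction(265000 + 407500, 2))

    def test_invalid_calibration_source_rejected(self):
        with pytest.raises(ValueError):
            GroupCostProfile("G1_full_pbp", 100, True, "guessed")
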