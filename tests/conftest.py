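import hypothesis
import pytest

from pbpcost import osset
from pbpcost.records import TraineeRecord

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def rates():
    return osset.DEFAULT_RATES


@pytest.fixture(scope="session")
def profiles(rates):
    return osset.printed_profiles(rates)


@pytest.fixture(scope="session")
def gen_params():
    return osset.generator_params()


def _record(i, group, trials, days=1.0, nights=1, proficient=True):
    return TraineeRecord(
        trainee_id=f"{group}-{i:03d}",
        group=group,
        trials=trials,
        hands_on_hours=0.5 * trials,
        billed_days=days,
        nights=nights,
        proficient=proficient,
    )


@pytest.fixture(scope="session")
def trial_like_records():
    """47 hand-built records with the trial's group sizes 12/12/11/12.

    Group 1 trial counts sum to 71 (mean 5.92); Group 4 has 7 of 12
    proficient, the non-proficient at the full 3.5-day allocation.
    """
    g1_trials = [6] * 11 + [5]  # sums to 71
    records = [_record(i, "G1_full_pbp", t) for i, t in enumerate(g1_trials)]
    records += [_record(i, "G2_elearning", 7, days=1.5) for i in range(12)]
    records += [_record(i, "G3_traditional", 12, days=1.5, nights=2) for i in range(11)]
    for i in range(12):
        proficient = i < 7
        records.append(
            _record(
                i,
                "G4_apprenticeship",
                15 if proficient else 30,
                days=2.5 if proficient else 3.5,
                nights=3 if proficient else 4,
                proficient=proficient,
            )
        )
    return records
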