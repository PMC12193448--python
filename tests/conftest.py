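import pytest
from hypothesis import HealthCheck, settings

from agestage import Cohort, IndividualRecord, preset, simulate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def control_cohort():
    """A 50-egg control cohort, fixed seed."""
    return simulate_cohort(preset("control"), 50, seed=7)


@pytest.fixture(scope="session")
def t36_cohort():
    return simulate_cohort(preset("t36"), 50, seed=7)


@pytest.fixture
def hand_cohort():
    """Three hand-built records used as a pencil-and-paper oracle.

    A: female laying (0, 2, 1) eggs from adult emergence at day 4.
    B: male emerging at day 5, adult 2.5 d.
    C: dies as a larva at age 1.5 d.
    """
    a = IndividualRecord(
        "A", "toy",
        {"egg": 1.0, "larva": 1.0, "protonymph": 1.0, "deutonymph": 1.0},
        sex="F", adult_duration=3.0, daily_fecundity={5: 2, 6: 1},
    )
    b = IndividualRecord(
        "B", "toy",
        {"egg": 1.5, "larva": 1.0, "protonymph": 1.5, "deutonymph": 1.0},
        sex="M", adult_duration=2.5,
    )
    c = IndividualRecord("C", "toy", {"egg": 1.0, "larva": 0.5})
    return Cohort("toy", [a, b, c], initial_n=3)
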