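"""Age-stage schedules, age-only schedules, e_xj and v_xj."""

import numpy as np
import pytest

from agestage import (
    Cohort,
    IndividualRecord,
    STAGES,
    age_schedules,
    build_schedule,
    estimate_parameters,
    life_expectancy,
    preset,
    reproductive_value,
    simulate_cohort,
)
from agestage.records import day_index

EGG = STAGES.index("egg")
FEMALE = STAGES.index("female")


def brute_force_expectancy(schedule):
    """Forward unit-mass propagation oracle for e_xj."""
    A, S = schedule.s.shape
    e = np.full((A, S), np.nan)
    for x in range(A):
        for j in range(S):
            if schedule.counts[x, j] == 0:
                continue
            mass = np.zeros(S)
            mass[j] = 1.0
            total = 0.0
            for i in range(x, A):
                total += mass.sum()
                mass = mass @ schedule.transitions[i]
            e[x, j] = total
    return e


def brute_force_reproductive_value(schedule, r):
    """Forward discounted-fecundity summation oracle for v_xj."""
    A, S = schedule.s.shape
    v = np.full((A, S), np.nan)
    for x in range(A):
        for j in range(S):
            if schedule.counts[x, j] == 0:
                continue
            mass = np.zeros(S)
            mass[j] = 1.0
            total = 0.0
            for i in range(x, A):
                total += np.exp(-r * (i + 1)) * float(mass @ schedule.f[i])
                mass = mass @ schedule.transitions[i]
            v[x, j] = np.exp(r * (x + 1)) * total
    return v


class TestBuildSchedule:
    def test_single_egg_death(self):
        rec = IndividualRecord("x", "ctl", {"egg": 2.0})
        schedule = build_schedule(Cohort("ctl", [rec], initial_n=1))
        assert schedule.s.shape[0] == 2
        assert np.all(schedule.s[:, EGG] == 1.0)
        assert schedule.s[:, EGG + 1 :].sum() == 0

    def test_no_hatch_cohort_occupies_only_egg_column(self):
        cohort = simulate_cohort(preset("t42"), 50, seed=7)
        schedule = build_schedule(cohort)
        assert schedule.s[:, EGG].sum() > 0
        assert schedule.s[:, EGG + 1 :].sum() == 0

    def test_hand_enumerated_matrix(self, hand_cohort):
        schedule = build_schedule(hand_cohort)
        s = schedule.s
        expected = np.zeros((8, 6))
        expected[0, EGG] = 3 / 3
        expected[1, EGG] = 1 / 3                     # B
        expected[1, STAGES.index("larva")] = 2 / 3    # A, C
        expected[2, STAGES.index("larva")] = 1 / 3
        expected[2, STAGES.index("protonymph")] = 1 / 3
        expected[3, STAGES.index("protonymph")] = 1 / 3
        expected[3, STAGES.index("deutonymph")] = 1 / 3
        expected[4, STAGES.index("deutonymph")] = 1 / 3
        expected[4, FEMALE] = 1 / 3
        expected[5, FEMALE] = 1 / 3
        expected[5, STAGES.index("male")] = 1 / 3
        expected[6, FEMALE] = 1 / 3
        expected[6, STAGES.index("male")] = 1 / 3
        expected[7, STAGES.index("male")] = 1 / 3
        np.testing.assert_allclose(s, expected)
        assert schedule.f[5, FEMALE] == 2.0   # 2 eggs / 1 female alive
        assert schedule.f[6, FEMALE] == 1.0
        assert schedule.f.sum() == 3.0

    def test_empty_cohort_rejected(self):
        cohort = Cohort.__new__(Cohort)
        cohort.treatment = "x"
        cohort.records = []
        cohort.initial_n = 0
        with pytest.raises(ValueError):
            build_schedule(cohort)


class TestAgeSchedules:
    def test_single_stage_block_survival(self):
        recs = [IndividualRecord(f"i{k}", "c", {"egg": 5.0}) for k in range(4)]
        ages = age_schedules(build_schedule(Cohort("c", recs, initial_n=4)))
        np.testing.assert_allclose(ages.lx, np.ones(5))

    def test_weighted_mean_identity(self, hand_cohort):
        ages = age_schedules(build_schedule(hand_cohort))
        # at age 5 only 2/3 of newborns are alive; only the female lays
        assert ages.mx[5] == pytest.approx(1.0)
        assert ages.lxmx[5] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("name,seed", [("control", 0), ("t38", 1), ("t40", 2)])
    def test_maternity_sum_equals_direct_egg_count(self, name, seed):
        cohort = simulate_cohort(preset(name), 60, seed=seed)
        ages = age_schedules(build_schedule(cohort))
        assert ages.lxmx.sum() == pytest.approx(
            cohort.total_eggs() / cohort.initial_n, abs=1e-12
        )

    def test_lx_non_increasing_and_conserved(self, control_cohort):
        schedule = build_schedule(control_cohort)
        ages = age_schedules(schedule)
        assert ages.lx[0] == 1.0
        assert np.all(np.diff(ages.lx) <= 1e-12)
        np.testing.assert_allclose(ages.lx, schedule.s.sum(axis=1))


class TestLifeExpectancy:
    def test_deterministic_lifespan(self):
        recs = [IndividualRecord(f"i{k}", "c", {"egg": 4.0}) for k in range(3)]
        e = life_expectancy(build_schedule(Cohort("c", recs, initial_n=3)))
        assert e[0, EGG] == pytest.approx(4.0)

    def test_boundary_last_day_expectancy_is_one(self, control_cohort):
        schedule = build_schedule(control_cohort)
        e = life_expectancy(schedule)
        last = schedule.max_age
        occupied = schedule.counts[last] > 0
        np.testing.assert_allclose(e[last, occupied], 1.0)

    @pytest.mark.parametrize("name,seed", [("control", 3), ("t36", 4)])
    def test_newborn_expectancy_is_mean_lifespan(self, name, seed):
        cohort = simulate_cohort(preset(name), 80, seed=seed)
        e = life_expectancy(build_schedule(cohort))
        mean_lifespan = np.mean([day_index(r.death_age) for r in cohort.records])
        assert e[0, EGG] == pytest.approx(mean_lifespan, abs=1e-9)

    def test_matches_forward_propagation_oracle(self, t36_cohort):
        schedule = build_schedule(t36_cohort)
        np.testing.assert_allclose(
            life_expectancy(schedule),
            brute_force_expectancy(schedule),
            atol=1e-9,
        )

    def test_undefined_entries_are_nan_not_zero(self, control_cohort):
        schedule = build_schedule(control_cohort)
        e = life_expectancy(schedule)
        empty = schedule.counts == 0
        assert np.all(np.isnan(e[empty]))
        assert not np.any(np.isnan(e[~empty]))


class TestReproductiveValue:
    def test_zero_when_no_reproduction(self):
        recs = [
            IndividualRecord(
                f"i{k}", "c",
                {"egg": 1.0, "larva": 1.0, "protonymph": 1.0, "deutonymph": 1.0},
                sex="M", adult_duration=3.0,
            )
            for k in range(3)
        ]
        schedule = build_schedule(Cohort("c", recs, initial_n=3))
        v = reproductive_value(schedule, r=0.1)
        occupied = schedule.counts > 0
        np.testing.assert_allclose(v[occupied], 0.0)

    def test_newborn_value_equals_lambda(self, control_cohort):
        params = estimate_parameters(control_cohort)
        schedule = build_schedule(control_cohort)
        v = reproductive_value(schedule, params.r)
        assert v[0, EGG] == pytest.approx(params.lam, rel=1e-8)

    def test_matches_brute_force_summation(self, hand_cohort):
        params = estimate_parameters(hand_cohort)
        schedule = build_schedule(hand_cohort)
        np.testing.assert_allclose(
            reproductive_value(schedule, params.r),
            brute_force_reproductive_value(schedule, params.r),
            atol=1e-10,
        )


@pytest.mark.parametrize("seed", [0, 1])
def test_e_and_v_invariant_to_record_order(seed):
    cohort = simulate_cohort(preset("t36"), 40, seed=seed)
    params = estimate_parameters(cohort)
    shuffled = Cohort(
        cohort.treatment, list(reversed(cohort.records)), cohort.initial_n
    )
    s1, s2 = build_schedule(cohort), build_schedule(shuffled)
    np.testing.assert_allclose(
        life_expectancy(s1), life_expectancy(s2), equal_nan=True
    )
    np.testing.assert_allclose(
        reproductive_value(s1, params.r),
        reproductive_value(s2, params.r),
        equal_nan=True,
    )
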