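"""Bootstrap SEs, the paired bootstrap test, and compact letter displays."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agestage import (
    Cohort,
    IndividualRecord,
    STATISTICS,
    bootstrap,
    compact_letters,
    paired_bootstrap_test,
    preset,
    simulate_cohort,
)


def constant_statistic(cohort):
    return float(cohort.initial_n)


def _lifespan_cohort(treatment, lifespans):
    recs = [
        IndividualRecord(f"{treatment}{i}", treatment, {"egg": d})
        for i, d in enumerate(lifespans)
    ]
    return Cohort(treatment, recs, initial_n=len(recs))


class TestBootstrap:
    def test_constant_statistic_has_zero_se(self, control_cohort):
        result = bootstrap(control_cohort, constant_statistic, B=200, seed=7)
        assert result.se == 0.0
        assert result.n_degenerate == 0

    def test_deterministic_given_seed(self, control_cohort):
        a = bootstrap(control_cohort, STATISTICS["fecundity"], B=300, seed=11)
        b = bootstrap(control_cohort, STATISTICS["fecundity"], B=300, seed=11)
        assert (a.se, a.boot_mean, a.n_degenerate) == (
            b.se, b.boot_mean, b.n_degenerate
        )

    def test_se_matches_closed_form_for_a_mean(self, control_cohort):
        """Bootstrap SE of a plain mean ~ s/sqrt(n) (within 10%)."""
        result = bootstrap(
            control_cohort, STATISTICS["mean_lifespan"], B=5000, seed=7
        )
        values = [r.death_age for r in control_cohort.records]
        closed_form = np.std(values, ddof=1) / math.sqrt(len(values))
        assert result.se == pytest.approx(closed_form, rel=0.10)

    def test_boot_mean_approaches_point_estimate(self, control_cohort):
        stat = STATISTICS["fecundity"]
        point = stat(control_cohort)
        errs = [
            abs(bootstrap(control_cohort, stat, B=B, seed=7).boot_mean - point)
            for B in (100, 1000, 10000)
        ]
        assert errs[-1] <= max(errs[0], 0.05)

    def test_degenerate_resamples_counted(self):
        # nearly-sterile cohort: many resamples carry no reproducing female
        recs = [
            IndividualRecord(
                "f", "x",
                {"egg": 1.0, "larva": 1.0, "protonymph": 1.0, "deutonymph": 1.0},
                sex="F", adult_duration=3.0, daily_fecundity={4: 2},
            )
        ] + [IndividualRecord(f"d{i}", "x", {"egg": 1.0}) for i in range(19)]
        cohort = Cohort("x", recs, initial_n=20)
        result = bootstrap(cohort, STATISTICS["r"], B=400, seed=7)
        assert result.n_degenerate > 0
        assert result.unreliable == (result.n_degenerate > 200)


class TestPairedTest:
    def test_identical_cohorts_not_significant(self, control_cohort):
        res = paired_bootstrap_test(
            control_cohort, control_cohort, STATISTICS["mean_lifespan"],
            B=500, seed=7,
        )
        assert res.p == 1.0
        assert not res.significant

    def test_disjoint_supports_reject(self):
        a = _lifespan_cohort("hi", [10.0 + 0.5 * i for i in range(20)])
        b = _lifespan_cohort("lo", [1.0 + 0.5 * (i % 4) for i in range(20)])
        res = paired_bootstrap_test(
            a, b, STATISTICS["mean_lifespan"], B=10_000, seed=7
        )
        assert res.p < 0.001
        assert res.significant

    def test_exchange_symmetry_bit_identical(self):
        a = simulate_cohort(preset("control"), 50, seed=21)
        b = simulate_cohort(preset("t40"), 50, seed=22)
        ab = paired_bootstrap_test(a, b, STATISTICS["fecundity"], B=800, seed=7)
        ba = paired_bootstrap_test(b, a, STATISTICS["fecundity"], B=800, seed=7)
        assert ab.p == ba.p
        assert ab.diff == -ba.diff
        assert ab.significant == ba.significant

    def test_unestimable_point_statistic_rejected(self):
        t42 = simulate_cohort(preset("t42"), 30, seed=7)
        ctl = simulate_cohort(preset("control"), 30, seed=7)
        with pytest.raises(ValueError, match="not estimable"):
            paired_bootstrap_test(ctl, t42, STATISTICS["r"], B=50, seed=7)


class TestCompactLetters:
    def test_no_significant_pairs_all_share(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        letters = compact_letters(means, lambda x, y: False)
        assert set(letters.values()) == {"a"}

    def test_all_pairs_distinct(self):
        means = {"ctl": 18.7, "t36": 16.0, "t38": 12.5, "t40": 9.6}
        letters = compact_letters(means, lambda x, y: True)
        assert letters == {"ctl": "a", "t36": "b", "t38": "c", "t40": "d"}

    def test_chain_pattern_multi_letter(self):
        means = {"t1": 3.0, "t2": 2.0, "t3": 1.0}
        sig = {frozenset(("t1", "t3")): True,
               frozenset(("t1", "t2")): False,
               frozenset(("t2", "t3")): False}
        assert compact_letters(means, sig) == {"t1": "a", "t2": "ab", "t3": "b"}

    def test_all_three_treatment_patterns_against_hand_solutions(self):
        means = {"t1": 3.0, "t2": 2.0, "t3": 1.0}
        hand = {
            (False, False, False): {"t1": "a", "t2": "a", "t3": "a"},
            (True, False, False): {"t1": "a", "t2": "b", "t3": "ab"},
            (False, True, False): {"t1": "a", "t2": "ab", "t3": "b"},
            (False, False, True): {"t1": "ab", "t2": "a", "t3": "b"},
            (True, True, False): {"t1": "a", "t2": "b", "t3": "b"},
            (True, False, True): {"t1": "a", "t2": "b", "t3": "a"},
            (False, True, True): {"t1": "a", "t2": "a", "t3": "b"},
            (True, True, True): {"t1": "a", "t2": "b", "t3": "c"},
        }
        pairs = [("t1", "t2"), ("t1", "t3"), ("t2", "t3")]
        for pattern, expected in hand.items():
            sig = {
                frozenset(pair): flag for pair, flag in zip(pairs, pattern)
            }
            assert compact_letters(means, sig) == expected, pattern

    @given(
        n=st.integers(min_value=2, max_value=6),
        bits=st.integers(min_value=0, max_value=2**15 - 1),
    )
    def test_share_letter_iff_not_significant(self, n, bits):
        """Defining property of a compact letter display, any pattern."""
        names = [f"t{i}" for i in range(n)]
        means = {t: float(n - i) for i, t in enumerate(names)}
        pairs = [
            (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        sig = {
            frozenset(pair): bool((bits >> k) & 1)
            for k, pair in enumerate(pairs)
        }
        letters = compact_letters(means, sig)
        for a, b in pairs:
            share = bool(set(letters[a]) & set(letters[b]))
            assert share != sig[frozenset((a, b))]
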