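"""Synthetic cohort generation for the four-temperature heat-stress design.

The generator emulates a life-table experiment on *Phytoseiulus persimilis*
in which cohorts of 50 eggs were exposed for four hours to 36, 38, 40 or
42 °C (plus an unstressed control), then followed at 12-h censuses through
development and daily through adult life.  Each preset encodes a
treatment's cohort-level calibration: hatch probability and stage-wise
survival apportioned from the published per-stage sample sizes, stage
duration and longevity distributions as truncated normals whose SDs are
backed out of the published standard errors (SD = SE·√n), the conditional
probability that an adult is female, and the lifetime fecundity target.
Eggs heat-shocked at 42 °C never hatch.

Per egg the generative model runs: hatch Bernoulli → per-stage survival
Bernoullis with truncated-normal durations discretised to the 0.5-day
census grid (death within a stage is placed at the end of a full drawn
duration — the failed moult) → sex Bernoulli at adulthood → sex-specific
adult duration → for females an adult pre-oviposition period, a number of
oviposition days placed with a triangular daily-fecundity profile peaking
at the treatment's observed peak age, and integer egg counts that sum
exactly to the drawn lifetime fecundity.  No between-trait correlation is
simulated beyond the structural constraint that laying fits inside the
adult life span.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .records import PREADULT_STAGES, Cohort, IndividualRecord

__all__ = [
    "SimulationConfig",
    "preset",
    "PRESET_NAMES",
    "simulate_cohort",
    "implied_preadult_survival",
    "implied_sex_ratio",
    "implied_R0",
    "expected_counts",
    "reconstruct_cohort",
]

_MASK31 = (1 << 31) - 1


@dataclass
class SimulationConfig:
    """Per-treatment generative parameters (all durations in days)."""

    treatment: str
    hatch_probability: float
    stage_durations: dict[str, tuple[float, float]]  # stage -> (mean, sd)
    stage_survival: dict[str, float]  # larva/protonymph/deutonymph -> p
    female_fraction: float  # P(adult is female)
    adult_duration: dict[str, tuple[float, float]]  # "F"/"M" -> (mean, sd)
    apop: tuple[float, float]
    oviposition_days: tuple[float, float]
    fecundity: tuple[float, float]
    peak_age: int  # age (days) of the daily-fecundity peak
    seed: int | None = None

    def validate(self) -> None:
        probs = [self.hatch_probability, self.female_fraction, *self.stage_survival.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if set(self.stage_durations) != set(PREADULT_STAGES):
            raise ValueError("stage_durations must cover all four pre-adult stages")
        for mean, sd in [
            *self.stage_durations.values(),
            *self.adult_duration.values(),
            self.apop,
            self.oviposition_days,
            self.fecundity,
        ]:
            if mean <= 0 or sd < 0:
                raise ValueError(f"distribution (mean={mean}, sd={sd}) invalid")


def _sd(se: float, n: int) -> float:
    return se * math.sqrt(n)


# Calibration: per-stage sample sizes, trait means and SEs from the
# four-temperature experiment (SD backed out as SE * sqrt(n)).
_PRESETS: dict[str, SimulationConfig] = {
    "control": SimulationConfig(
        treatment="control",
        hatch_probability=49 / 50,
        stage_durations={
            "egg": (1.83, _sd(0.05, 49)),
            "larva": (1.10, _sd(0.05, 47)),
            "protonymph": (1.69, _sd(0.09, 37)),
            "deutonymph": (1.85, _sd(0.05, 33)),
        },
        stage_survival={"larva": 47 / 49, "protonymph": 37 / 47, "deutonymph": 33 / 37},
        female_fraction=24 / 33,
        adult_duration={"F": (19.92, _sd(0.64, 24)), "M": (15.33, _sd(0.29, 9))},
        apop=(2.65, _sd(0.09, 24)),
        oviposition_days=(14.50, _sd(0.55, 24)),
        fecundity=(39.0, _sd(1.39, 24)),
        peak_age=23,
    ),
    "t36": SimulationConfig(
        treatment="t36",
        hatch_probability=47 / 50,
        stage_durations={
            "egg": (1.52, _sd(0.09, 47)),
            "larva": (1.08, _sd(0.07, 47)),
            "protonymph": (1.64, _sd(0.10, 40)),
            "deutonymph": (1.74, _sd(0.08, 35)),
        },
        stage_survival={"larva": 47 / 47, "protonymph": 40 / 47, "deutonymph": 35 / 40},
        female_fraction=25 / 35,
        adult_duration={"F": (16.50, _sd(0.48, 25)), "M": (12.40, _sd(0.16, 10))},
        apop=(2.70, _sd(0.09, 25)),
        oviposition_days=(9.28, _sd(0.33, 25)),
        fecundity=(32.08, _sd(1.23, 25)),
        peak_age=18,
    ),
    "t38": SimulationConfig(
        treatment="t38",
        hatch_probability=46 / 50,
        stage_durations={
            "egg": (1.71, _sd(0.06, 46)),
            "larva": (0.93, _sd(0.05, 42)),
            "protonymph": (1.38, _sd(0.08, 39)),
            "deutonymph": (1.56, _sd(0.07, 34)),
        },
        stage_survival={"larva": 42 / 46, "protonymph": 39 / 42, "deutonymph": 34 / 39},
        female_fraction=24 / 34,
        adult_duration={"F": (15.46, _sd(0.39, 24)), "M": (11.45, _sd(0.23, 10))},
        apop=(2.75, _sd(0.06, 24)),
        oviposition_days=(9.31, _sd(0.25, 24)),
        fecundity=(25.96, _sd(0.77, 24)),
        peak_age=18,
    ),
    "t40": SimulationConfig(
        treatment="t40",
        hatch_probability=45 / 50,
        stage_durations={
            "egg": (1.39, _sd(0.10, 45)),
            "larva": (0.86, _sd(0.07, 44)),
            "protonymph": (1.45, _sd(0.13, 39)),
            "deutonymph": (1.59, _sd(0.08, 31)),
        },
        stage_survival={"larva": 44 / 45, "protonymph": 39 / 44, "deutonymph": 31 / 39},
        female_fraction=22 / 31,
        adult_duration={"F": (14.55, _sd(0.38, 22)), "M": (10.78, _sd(0.28, 9))},
        apop=(2.00, _sd(0.05, 22)),
        oviposition_days=(7.00, _sd(0.22, 22)),
        fecundity=(21.82, _sd(0.75, 22)),
        peak_age=16,
    ),
    # 42 °C: no egg hatches.  The egg "duration" is the survival time of the
    # unhatched egg under observation; downstream fields are unused.
    "t42": SimulationConfig(
        treatment="t42",
        hatch_probability=0.0,
        stage_durations={
            "egg": (1.83, 0.35),
            "larva": (1.10, 0.34),
            "protonymph": (1.69, 0.55),
            "deutonymph": (1.85, 0.29),
        },
        stage_survival={"larva": 0.0, "protonymph": 0.0, "deutonymph": 0.0},
        female_fraction=0.5,
        adult_duration={"F": (19.92, 3.1), "M": (15.33, 0.9)},
        apop=(2.65, 0.44),
        oviposition_days=(14.50, 2.7),
        fecundity=(39.0, 6.8),
        peak_age=23,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> SimulationConfig:
    """Return a fresh copy of a named treatment preset."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    cfg = _PRESETS[name]
    return replace(
        cfg,
        stage_durations=dict(cfg.stage_durations),
        stage_survival=dict(cfg.stage_survival),
        adult_duration=dict(cfg.adult_duration),
    )


def implied_preadult_survival(config: SimulationConfig) -> float:
    """Egg-to-adult survival implied by the config's Bernoulli chain."""
    p = config.hatch_probability
    for stage in ("larva", "protonymph", "deutonymph"):
        p *= config.stage_survival[stage]
    return p


def implied_sex_ratio(config: SimulationConfig) -> float:
    """Per-newborn probability of becoming an adult female."""
    return implied_preadult_survival(config) * config.female_fraction


def implied_R0(config: SimulationConfig) -> float:
    """Closed-form net reproductive rate: P(female) x mean fecundity."""
    return implied_sex_ratio(config) * config.fecundity[0]


def _rng_for(config: SimulationConfig, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed & _MASK31, zlib.crc32(config.treatment.encode()) & _MASK31]
        )
    )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at > 0 (rejection sampling)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def _half_day(x: float) -> float:
    """Discretise to the 0.5-day census grid, minimum half a day."""
    return max(0.5, round(x * 2) / 2)


def _curve_weight(day: int, peak: int) -> float:
    """Triangular daily-fecundity profile with a floor, peaking at `peak`."""
    return max(0.05, 1.0 - abs(day - peak) / 15.0)


def _simulate_female_laying(
    rng: np.random.Generator,
    config: SimulationConfig,
    emergence: float,
    death_age: float,
) -> dict[int, int]:
    apop = _draw_positive(rng, *config.apop)
    first_day = int(math.floor(emergence + apop + 0.5))
    last_day = math.ceil(death_age) - 1 if death_age == int(death_age) else int(death_age)
    if first_day > last_day:
        return {}
    available = list(range(first_day, last_day + 1))
    k = max(1, round(_draw_positive(rng, *config.oviposition_days)))
    k = min(k, len(available))
    total = max(1, round(_draw_positive(rng, *config.fecundity)))
    k = min(k, total)
    weights = np.array([_curve_weight(d, config.peak_age) for d in available])
    # the first oviposition day is fixed by definition; sample the rest
    rest = available[1:]
    if k - 1 > 0 and rest:
        w = weights[1:] / weights[1:].sum()
        chosen_rest = rng.choice(len(rest), size=k - 1, replace=False, p=w)
        days = sorted([available[0]] + [rest[i] for i in chosen_rest])
    else:
        days = [available[0]]
    day_w = np.array([_curve_weight(d, config.peak_age) for d in days])
    extra = rng.multinomial(total - len(days), day_w / day_w.sum())
    return {d: 1 + int(e) for d, e in zip(days, extra)}


def simulate_cohort(
    config: SimulationConfig, n: int, seed: int | None = None
) -> Cohort:
    """Simulate a cohort of ``n`` eggs under a treatment configuration.

    Deterministic given (config, n, seed); the returned cohort satisfies
    every cohort invariant (it passes full validation on construction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    rng = _rng_for(config, seed)
    records: list[IndividualRecord] = []
    for i in range(n):
        ind_id = f"{config.treatment}_{i:04d}"
        durations: dict[str, float] = {}
        d_egg = _half_day(_draw_positive(rng, *config.stage_durations["egg"]))
        durations["egg"] = d_egg
        if rng.random() >= config.hatch_probability:
            records.append(
                IndividualRecord(ind_id, config.treatment, durations)
            )
            continue
        died = False
        for stage in ("larva", "protonymph", "deutonymph"):
            d = _half_day(_draw_positive(rng, *config.stage_durations[stage]))
            durations[stage] = d
            if rng.random() >= config.stage_survival[stage]:
                died = True
                break
        if died:
            records.append(
                IndividualRecord(ind_id, config.treatment, durations)
            )
            continue
        sex = "F" if rng.random() < config.female_fraction else "M"
        adult_d = _half_day(_draw_positive(rng, *config.adult_duration[sex]))
        emergence = sum(durations.values())
        fecundity: dict[int, int] = {}
        if sex == "F":
            fecundity = _simulate_female_laying(
                rng, config, emergence, emergence + adult_d
            )
        records.append(
            IndividualRecord(
                ind_id,
                config.treatment,
                durations,
                sex=sex,
                adult_duration=adult_d,
                daily_fecundity=fecundity,
            )
        )
    return Cohort(treatment=config.treatment, records=records, initial_n=n)


def expected_counts(config: SimulationConfig, n: int) -> dict[str, int]:
    """Cohort-level counts implied by a config at cohort size n.

    Rounds the survival chain stage by stage, reproducing the integer
    per-stage sample sizes the calibration was built from.
    """
    hatched = round(n * config.hatch_probability)
    larva = round(hatched * config.stage_survival["larva"])
    proto = round(larva * config.stage_survival["protonymph"])
    adults = round(proto * config.stage_survival["deutonymph"])
    females = round(adults * config.female_fraction)
    return {
        "initial_n": n,
        "egg": hatched,
        "larva": larva,
        "protonymph": proto,
        "deutonymph": adults,
        "females": females,
        "males": adults - females,
        "total_eggs": round(females * config.fecundity[0]),
    }


def reconstruct_cohort(config: SimulationConfig, n: int = 50) -> Cohort:
    """Deterministic cohort whose marginal counts match ``expected_counts``.

    A synthetic stand-in for the unpublished individual-level data: stage
    completion counts, adult sex counts and the total egg output agree
    exactly with the config's calibration at cohort size n, while stage
    durations are fixed nominal values.  Useful for exercising the exact
    count-based identities (R0 = F·N_f/N, survival and sex-ratio ratios)
    through the full pipeline.
    """
    counts = expected_counts(config, n)
    durations = {"egg": 2.0, "larva": 1.0, "protonymph": 1.5, "deutonymph": 2.0}
    records: list[IndividualRecord] = []
    k = 0

    def next_id() -> str:
        nonlocal k
        k += 1
        return f"{config.treatment}_r{k:03d}"

    stage_order = ("egg", "larva", "protonymph", "deutonymph")
    completers = [counts[s] for s in stage_order]
    deaths = [n - completers[0]] + [
        completers[i] - completers[i + 1] for i in range(3)
    ]
    for stage_idx, n_dead in enumerate(deaths):
        prefix = stage_order[: stage_idx + 1]
        for _ in range(n_dead):
            records.append(
                IndividualRecord(
                    next_id(),
                    config.treatment,
                    {s: durations[s] for s in prefix},
                )
            )
    emergence = sum(durations.values())  # 6.5 -> adult from day 7
    first_day = int(emergence) + 3  # day 9: after a nominal pre-oviposition lag
    quota, remainder = divmod(counts["total_eggs"], max(counts["females"], 1))
    for i in range(counts["females"]):
        eggs_total = quota + (1 if i < remainder else 0)
        fecundity: dict[int, int] = {}
        day = first_day
        left = eggs_total
        while left > 0:
            laid = min(3, left)
            fecundity[day] = laid
            left -= laid
            day += 1
        records.append(
            IndividualRecord(
                next_id(),
                config.treatment,
                dict(durations),
                sex="F",
                adult_duration=20.0,
                daily_fecundity=fecundity,
            )
        )
    for _ in range(counts["males"]):
        records.append(
            IndividualRecord(
                next_id(),
                config.treatment,
                dict(durations),
                sex="M",
                adult_duration=15.0,
            )
        )
    return Cohort(treatment=config.treatment, records=records, initial_n=n)
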