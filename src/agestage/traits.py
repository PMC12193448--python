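"""Per-treatment biological trait statistics.

Means, conventional standard errors (sample SD / sqrt(n)) and the number of
contributing individuals for: stage development times, total pre-adult
duration, pre-adult survival, adult durations and longevities by sex,
lifetime fecundity, the adult and total pre-oviposition periods (APOP,
TPOP), oviposition days, and the sex ratio.

Conventions mirroring the underlying two-sex framework:

* every per-stage statistic is over the individuals that *completed* that
  stage, at the raw 0.5-day census resolution;
* the sex ratio is females reaching adulthood over the initial egg count,
  which makes mean fecundity x sex ratio = R0 an exact identity;
* females that never laid contribute a 0 to the fecundity mean but are
  excluded from APOP/TPOP/oviposition-day statistics, which are defined
  only for females that laid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records import PREADULT_STAGES, Cohort, IndividualRecord

__all__ = [
    "TraitStat",
    "stage_durations",
    "preadult_duration",
    "preadult_survival",
    "adult_durations",
    "longevities",
    "oviposition_stats",
    "sex_ratio",
    "trait_table",
]


@dataclass(frozen=True)
class TraitStat:
    mean: float
    se: float
    n: int


def _stat(values: list[float]) -> TraitStat:
    n = len(values)
    if n == 0:
        return TraitStat(math.nan, math.nan, 0)
    mean = sum(values) / n
    if n == 1:
        return TraitStat(mean, math.nan, 1)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return TraitStat(mean, math.sqrt(var / n), n)


def stage_durations(cohort: Cohort) -> dict[str, TraitStat]:
    """Mean development time of each pre-adult stage, over completers."""
    out: dict[str, TraitStat] = {}
    for stage in PREADULT_STAGES:
        values = [
            r.stage_durations[stage]
            for r in cohort.records
            if stage in r.completed_stages()
        ]
        out[stage] = _stat(values)
    return out


def preadult_duration(cohort: Cohort) -> TraitStat:
    """Total egg-to-adult development time, over individuals reaching adulthood."""
    return _stat([r.preadult_duration for r in cohort.adults()])


def preadult_survival(cohort: Cohort) -> float:
    """Proportion of initial eggs that reached adulthood."""
    return len(cohort.adults()) / cohort.initial_n


def adult_durations(cohort: Cohort) -> dict[str, TraitStat]:
    """Adult-stage duration by sex."""
    return {
        "F": _stat([r.adult_duration for r in cohort.females()]),
        "M": _stat([r.adult_duration for r in cohort.males()]),
    }


def longevities(cohort: Cohort) -> dict[str, TraitStat]:
    """Total lifespan (pre-adult + adult) by sex."""
    return {
        "F": _stat([r.death_age for r in cohort.females()]),
        "M": _stat([r.death_age for r in cohort.males()]),
    }


def _first_egg_day(rec: IndividualRecord) -> int | None:
    if not rec.daily_fecundity:
        return None
    return min(d for d, eggs in rec.daily_fecundity.items() if eggs > 0)


def oviposition_stats(cohort: Cohort) -> dict[str, TraitStat]:
    """Fecundity, APOP, TPOP and oviposition days over females.

    fecundity — lifetime eggs per female (all females, 0 for non-layers);
    APOP — age at first egg minus age at adult emergence;
    TPOP — age at first egg (from the female's own egg stage);
    oviposition_days — number of days with at least one egg.
    APOP/TPOP/oviposition_days are over ovipositing females only.
    """
    females = cohort.females()
    if not females:
        raise ValueError("cohort has no females")
    fecundity = [float(sum(r.daily_fecundity.values())) for r in females]
    apop: list[float] = []
    tpop: list[float] = []
    ovi_days: list[float] = []
    for rec in females:
        first = _first_egg_day(rec)
        if first is None:
            continue
        apop.append(first - rec.preadult_duration)
        tpop.append(float(first))
        ovi_days.append(float(sum(1 for e in rec.daily_fecundity.values() if e > 0)))
    return {
        "fecundity": _stat(fecundity),
        "APOP": _stat(apop),
        "TPOP": _stat(tpop),
        "oviposition_days": _stat(ovi_days),
    }


def sex_ratio(cohort: Cohort) -> float:
    """Proportion of the initial egg cohort that became adult females."""
    return len(cohort.females()) / cohort.initial_n


def trait_table(cohort: Cohort):
    """All trait statistics as a tidy DataFrame: trait, treatment, mean, se, n."""
    import pandas as pd

    rows: list[tuple] = []

    def add(trait: str, stat: TraitStat) -> None:
        rows.append((trait, cohort.treatment, stat.mean, stat.se, stat.n))

    for stage, stat in stage_durations(cohort).items():
        add(f"{stage}_duration", stat)
    add("preadult_duration", preadult_duration(cohort))
    rows.append(
        (
            "preadult_survival",
            cohort.treatment,
            preadult_survival(cohort),
            math.nan,
            cohort.initial_n,
        )
    )
    for sex, stat in adult_durations(cohort).items():
        add(f"adult_duration_{sex}", stat)
    for sex, stat in longevities(cohort).items():
        add(f"longevity_{sex}", stat)
    if cohort.females():
        for trait, stat in oviposition_stats(cohort).items():
            add(trait, stat)
    rows.append(
        ("sex_ratio", cohort.treatment, sex_ratio(cohort), math.nan, cohort.initial_n)
    )
    return pd.DataFrame(rows, columns=["trait", "treatment", "mean", "se", "n"])
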