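"""Age-stage schedules and the derived life-table functions.

The age-stage, two-sex framework keeps survival and fecundity resolved by
both age x (whole days since the egg was laid) and stage j, so that
variable development rates and the male half of the cohort are represented
instead of being averaged away.  The core objects are

* ``s_xj`` — probability that a newborn egg is alive *and in stage j* at
  age x (denominator: the initial egg count, so never-hatched eggs and
  pre-adult deaths depress it);
* ``f_xj`` — mean eggs laid per day by an individual of age x in stage j
  (nonzero only in the female-adult column);
* ``l_x = Σ_j s_xj`` and ``m_x = Σ_j s_xj f_xj / Σ_j s_xj`` — the classical
  age-only schedules recovered by summing over stages;
* ``e_xj`` — expected remaining lifetime at (x, j), from the cohort's own
  empirical daily stage-transition behaviour (the current day counts);
* ``v_xj`` — reproductive value at (x, j): expected discounted future egg
  output per individual now at (x, j), discounted at the intrinsic rate r.

Entries of e and v at (x, j) combinations no individual ever occupied are
undefined and reported as NaN, never 0 — zero is a meaningful value here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import STAGES, Cohort, IndividualRecord, day_index

__all__ = [
    "AgeStageSchedule",
    "AgeSchedule",
    "build_schedule",
    "age_schedules",
    "life_expectancy",
    "reproductive_value",
    "occupancy",
    "schedule_frame",
    "ages_frame",
]

_FEMALE = STAGES.index("female")


def occupancy(record: IndividualRecord) -> list[tuple[int, int]]:
    """Daily stage occupancy of one individual on the whole-day grid.

    Returns ``(day, stage_index)`` pairs for every day the individual is
    alive.  Stage boundaries are the cumulative half-day durations rounded
    half-up; on a day when a moult falls, the individual is assigned to the
    later stage (the transition happens at the start of the rounded day).
    An individual dying at age D occupies days 0 .. day_index(D) - 1.
    """
    out: list[tuple[int, int]] = []
    cum = 0.0
    start_day = 0
    stages = list(record.stage_durations.items())
    if record.adult_duration is not None:
        stages.append(("female" if record.sex == "F" else "male", record.adult_duration))
    for stage, dur in stages:
        cum += dur
        end_day = day_index(cum)
        j = STAGES.index(stage)
        for day in range(start_day, end_day):
            out.append((day, j))
        start_day = end_day
    return out


@dataclass
class AgeStageSchedule:
    """Matrices s_xj and f_xj on the daily age grid, plus cohort context.

    ``s`` and ``f`` have shape (max_age + 1, len(STAGES)); ``counts`` holds
    the raw number of individuals observed at each (x, j), needed to derive
    the empirical transition probabilities behind e_xj and v_xj.
    """

    treatment: str
    initial_n: int
    s: np.ndarray
    f: np.ndarray
    counts: np.ndarray
    transitions: np.ndarray  # (max_age+1, n_stages, n_stages) row-stochastic or sub-

    @property
    def max_age(self) -> int:
        return self.s.shape[0] - 1

    @property
    def stages(self) -> tuple[str, ...]:
        return STAGES


@dataclass
class AgeSchedule:
    """Age-only survival (l_x), fecundity (m_x) and maternity (l_x m_x)."""

    lx: np.ndarray
    mx: np.ndarray
    lxmx: np.ndarray


def build_schedule(cohort: Cohort) -> AgeStageSchedule:
    """Tabulate s_xj and f_xj from individual records.

    Denominator for s is the initial egg count; fecundity f at (x, female)
    is total eggs laid at age x divided by the number of females alive (in
    the female-adult stage) at age x.
    """
    if cohort.initial_n <= 0:
        raise ValueError("cohort initial_n must be positive")
    if not cohort.records:
        raise ValueError("cohort has no records")
    occs = [occupancy(rec) for rec in cohort.records]
    max_age = 0
    for occ in occs:
        if occ:
            max_age = max(max_age, occ[-1][0])
    n_stages = len(STAGES)
    counts = np.zeros((max_age + 1, n_stages), dtype=float)
    eggs = np.zeros(max_age + 1, dtype=float)
    trans = np.zeros((max_age + 1, n_stages, n_stages), dtype=float)
    for rec, occ in zip(cohort.records, occs):
        for (day, j) in occ:
            counts[day, j] += 1
        for (d0, j0), (d1, j1) in zip(occ, occ[1:]):
            trans[d0, j0, j1] += 1
        for age_day, n_eggs in rec.daily_fecundity.items():
            eggs[age_day] += n_eggs
    s = counts / cohort.initial_n
    f = np.zeros_like(s)
    fem = counts[:, _FEMALE]
    with np.errstate(invalid="ignore", divide="ignore"):
        f[:, _FEMALE] = np.where(fem > 0, eggs / np.where(fem > 0, fem, 1.0), 0.0)
    if np.any((eggs > 0) & (fem == 0)):
        bad = int(np.nonzero((eggs > 0) & (fem == 0))[0][0])
        raise ValueError(f"eggs recorded at age {bad} with no female alive")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = counts[:, :, None]
        p = np.where(denom > 0, trans / np.where(denom > 0, denom, 1.0), 0.0)
    return AgeStageSchedule(
        treatment=cohort.treatment,
        initial_n=cohort.initial_n,
        s=s,
        f=f,
        counts=counts,
        transitions=p,
    )


def age_schedules(schedule: AgeStageSchedule) -> AgeSchedule:
    """Collapse the age-stage matrices to l_x, m_x and l_x m_x."""
    lx = schedule.s.sum(axis=1)
    lxmx = (schedule.s * schedule.f).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(lx > 0, lxmx / np.where(lx > 0, lx, 1.0), 0.0)
    return AgeSchedule(lx=lx, mx=mx, lxmx=lxmx)


def life_expectancy(schedule: AgeStageSchedule) -> np.ndarray:
    """Age-stage life expectancy e_xj, counting the current day.

    Backward recursion on the cohort's empirical daily transitions:
    e_xj = 1 + Σ_y P[x, j, y] · e_{x+1, y}, with zero expectation beyond
    the last observed age.  Equivalent to placing unit mass at (x, j),
    propagating it forward with the observed transition frequencies, and
    summing the surviving mass over all later ages.  NaN where no
    individual was ever observed at (x, j).
    """
    A, n_stages = schedule.s.shape
    e = np.full((A, n_stages), np.nan)
    nxt = np.zeros(n_stages)
    for x in range(A - 1, -1, -1):
        here = 1.0 + schedule.transitions[x] @ nxt
        alive = schedule.counts[x] > 0
        e[x, alive] = here[alive]
        nxt = np.where(alive, here, 0.0)
    return e


def reproductive_value(schedule: AgeStageSchedule, r: float) -> np.ndarray:
    """Age-stage reproductive value v_xj at intrinsic rate r.

    v_xj weighs the expected future daily egg output of an individual now
    at (x, j) by e^{-r·(age at laying + 1)} and rescales by e^{r(x+1)}, so
    a newborn egg has v_{0,egg} = λ = e^r when r solves the Euler–Lotka
    equation.  Computed by the same backward recursion as e_xj on the
    discounted fecundity stream.  NaN where (x, j) was never occupied;
    exactly 0 at post-reproductive (x, j).
    """
    A, n_stages = schedule.s.shape
    v = np.full((A, n_stages), np.nan)
    nxt = np.zeros(n_stages)
    for x in range(A - 1, -1, -1):
        w = np.exp(-r * (x + 1)) * schedule.f[x] + schedule.transitions[x] @ nxt
        alive = schedule.counts[x] > 0
        v[x, alive] = np.exp(r * (x + 1)) * w[alive]
        nxt = np.where(alive, w, 0.0)
    return v


def schedule_frame(schedule: AgeStageSchedule):
    """Long-format export of s_xj / f_xj: columns age_day, stage, s, f."""
    import pandas as pd

    rows = []
    for x in range(schedule.max_age + 1):
        for j, stage in enumerate(STAGES):
            rows.append((x, stage, schedule.s[x, j], schedule.f[x, j]))
    return pd.DataFrame(rows, columns=["age_day", "stage", "s", "f"])


def ages_frame(ages: AgeSchedule):
    """Export of the age-only schedules: columns age_day, lx, mx, lxmx."""
    import pandas as pd

    return pd.DataFrame(
        {
            "age_day": np.arange(len(ages.lx)),
            "lx": ages.lx,
            "mx": ages.mx,
            "lxmx": ages.lxmx,
        }
    )
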