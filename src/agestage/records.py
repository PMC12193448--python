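"""Cohort life-history records: data model, validation, and CSV ingestion.

An individual's life history is recorded from the egg stage at 12-hour
censuses (durations on a 0.5-day grid) and daily fecundity counts for
females.  A cohort is the set of individuals started together as eggs under
one treatment; the number of eggs started (``initial_n``) is the denominator
for every population-level rate, so it is stored explicitly rather than
inferred from the record count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

__all__ = [
    "PREADULT_STAGES",
    "STAGES",
    "IndividualRecord",
    "Cohort",
    "CohortValidationError",
    "day_index",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: Pre-adult stages in developmental order.
PREADULT_STAGES = ("egg", "larva", "protonymph", "deutonymph")

#: Life-table stage axis: pre-adult stages followed by the two adult stages.
STAGES = PREADULT_STAGES + ("female", "male")

_SEXES = ("F", "M", "U")

_RECORD_COLUMNS = [
    "individual_id",
    "treatment",
    "egg_d",
    "larva_d",
    "protonymph_d",
    "deutonymph_d",
    "sex",
    "adult_d",
    "excluded",
]
_FECUNDITY_COLUMNS = ["individual_id", "age_day", "eggs"]


class CohortValidationError(ValueError):
    """Raised when records or cohort files violate the data contract."""


def day_index(age: float) -> int:
    """Map a half-day-resolution age to its whole-day life-table age class.

    Census ages come in 0.5-day steps; the life table runs on whole days.
    Half-day values round half-up (1.5 -> 2), so a moult or death observed
    at the mid-day census is attributed to the following day class.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    half_steps = round(age * 2)
    if abs(age * 2 - half_steps) > 1e-9:
        raise ValueError(f"age must be a multiple of 0.5 days, got {age}")
    return (half_steps + 1) // 2


def _is_half_grid(x: float) -> bool:
    return abs(x * 2 - round(x * 2)) <= 1e-9


@dataclass
class IndividualRecord:
    """One individual's full life history within a cohort.

    ``stage_durations`` is a developmental prefix: an individual that died
    as a larva has entries for egg and larva only, the final entry being the
    time survived in the stage of death.  ``sex`` is ``"U"`` (unknown) for
    individuals that died before adulthood, in which case ``adult_duration``
    is absent and ``daily_fecundity`` empty.  ``daily_fecundity`` maps
    whole-day age since the egg was laid to the number of eggs laid that day
    (positive entries only).
    """

    individual_id: str
    treatment: str
    stage_durations: dict[str, float]
    sex: str = "U"
    adult_duration: float | None = None
    daily_fecundity: dict[int, int] = field(default_factory=dict)
    excluded: bool = False

    @property
    def death_age(self) -> float:
        """Age at death in days: sum of stage durations plus adult time."""
        total = sum(self.stage_durations.values())
        if self.adult_duration is not None:
            total += self.adult_duration
        return total

    @property
    def preadult_duration(self) -> float | None:
        """Total pre-adult development time; None unless adulthood reached."""
        if self.sex == "U":
            return None
        return sum(self.stage_durations.values())

    def completed_stages(self) -> tuple[str, ...]:
        """Pre-adult stages this individual moulted out of."""
        n_present = len(self.stage_durations)
        if self.sex != "U":
            return PREADULT_STAGES  # reached adulthood: all four completed
        return PREADULT_STAGES[: max(n_present - 1, 0)]

    def validate(self) -> None:
        if self.excluded:
            if self.stage_durations or self.daily_fecundity or self.adult_duration:
                raise CohortValidationError(
                    f"{self.individual_id}: excluded individuals carry no data"
                )
            return
        if self.sex not in _SEXES:
            raise CohortValidationError(
                f"{self.individual_id}: sex must be one of {_SEXES}, got {self.sex!r}"
            )
        n = len(self.stage_durations)
        if n == 0:
            raise CohortValidationError(
                f"{self.individual_id}: at least the egg stage must be recorded"
            )
        if tuple(self.stage_durations) != PREADULT_STAGES[:n]:
            raise CohortValidationError(
                f"{self.individual_id}: stage durations must be a prefix of "
                f"{PREADULT_STAGES}, got {tuple(self.stage_durations)}"
            )
        for stage, d in self.stage_durations.items():
            if d < 0 or not _is_half_grid(d):
                raise CohortValidationError(
                    f"{self.individual_id}: {stage} duration {d} is not a "
                    "non-negative multiple of 0.5"
                )
        if self.sex == "U":
            if self.adult_duration is not None:
                raise CohortValidationError(
                    f"{self.individual_id}: adult duration present but sex unknown"
                )
            if self.daily_fecundity:
                raise CohortValidationError(
                    f"{self.individual_id}: fecundity recorded for a pre-adult death"
                )
        else:
            if n != len(PREADULT_STAGES):
                raise CohortValidationError(
                    f"{self.individual_id}: adults must have all four pre-adult "
                    f"stage durations, found {n}"
                )
            if self.adult_duration is None:
                raise CohortValidationError(
                    f"{self.individual_id}: adult individual lacks adult duration"
                )
            if self.adult_duration < 0 or not _is_half_grid(self.adult_duration):
                raise CohortValidationError(
                    f"{self.individual_id}: adult duration {self.adult_duration} "
                    "is not a non-negative multiple of 0.5"
                )
        if self.sex != "F" and self.daily_fecundity:
            raise CohortValidationError(
                f"{self.individual_id}: fecundity recorded for sex {self.sex!r}"
            )
        if self.daily_fecundity:
            emergence = self.preadult_duration
            death = self.death_age
            for age_day, eggs in self.daily_fecundity.items():
                if not isinstance(age_day, int) or age_day < 0:
                    raise CohortValidationError(
                        f"{self.individual_id}: fecundity age {age_day!r} must be "
                        "a non-negative whole-day age"
                    )
                if not isinstance(eggs, int) or eggs < 0:
                    raise CohortValidationError(
                        f"{self.individual_id}: egg count {eggs!r} at age "
                        f"{age_day} must be a non-negative integer"
                    )
                if age_day < emergence or age_day >= death:
                    raise CohortValidationError(
                        f"{self.individual_id}: eggs at age {age_day} outside the "
                        f"adult life span [{emergence}, {death})"
                    )


@dataclass
class Cohort:
    """A treatment-labelled collection of individual records.

    ``initial_n`` is the number of eggs the cohort started with.  It exceeds
    ``len(records)`` only when individuals were explicitly excluded (lost to
    handling); those placeholders are dropped from ``records`` at ingest but
    still count in every per-newborn denominator.
    """

    treatment: str
    records: list[IndividualRecord]
    initial_n: int

    def __post_init__(self) -> None:
        validate_cohort(self)

    @property
    def n_excluded(self) -> int:
        return self.initial_n - len(self.records)

    def females(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.sex == "F"]

    def males(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.sex == "M"]

    def adults(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.sex != "U"]

    def total_eggs(self) -> int:
        return sum(sum(r.daily_fecundity.values()) for r in self.records)


def validate_cohort(cohort: Cohort) -> None:
    """Check every cohort invariant, raising on the first violation."""
    if cohort.initial_n <= 0:
        raise CohortValidationError("initial_n must be positive")
    if not cohort.records:
        raise CohortValidationError("cohort has no records")
    if cohort.initial_n < len(cohort.records):
        raise CohortValidationError(
            f"initial_n={cohort.initial_n} smaller than record count "
            f"{len(cohort.records)}"
        )
    seen: set[str] = set()
    for rec in cohort.records:
        if rec.treatment != cohort.treatment:
            raise CohortValidationError(
                f"{rec.individual_id}: treatment {rec.treatment!r} does not "
                f"match cohort treatment {cohort.treatment!r}"
            )
        if rec.individual_id in seen:
            raise CohortValidationError(
                f"duplicate individual_id {rec.individual_id!r}"
            )
        seen.add(rec.individual_id)
        rec.validate()


def _format_duration(x: float | None) -> str:
    if x is None:
        return ""
    return f"{x:g}"


def write_cohort(cohort: Cohort, records_path, fecundity_path) -> None:
    """Write a cohort to the two-file CSV schema (records + fecundity)."""
    with open(records_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_RECORD_COLUMNS)
        for rec in cohort.records:
            row = [rec.individual_id, rec.treatment]
            for stage in PREADULT_STAGES:
                row.append(_format_duration(rec.stage_durations.get(stage)))
            row.append(rec.sex)
            row.append(_format_duration(rec.adult_duration))
            row.append("0")
            w.writerow(row)
        for k in range(cohort.n_excluded):
            w.writerow([f"excluded_{k}", cohort.treatment, "", "", "", "", "", "", "1"])
    with open(fecundity_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_FECUNDITY_COLUMNS)
        for rec in cohort.records:
            for age_day in sorted(rec.daily_fecundity):
                w.writerow([rec.individual_id, age_day, rec.daily_fecundity[age_day]])


def _parse_duration(cell: str, where: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise CohortValidationError(f"{where}: cannot parse duration {cell!r}") from None


def read_cohort(records_path, fecundity_path, treatment: str | None = None) -> Cohort:
    """Read and validate a cohort from the two-file CSV schema.

    ``initial_n`` is the number of rows in the records file, excluded
    placeholders included.  Fecundity rows are joined to female records by
    ``individual_id``; a row referencing a non-female or unknown individual
    is a validation error naming the offender.
    """
    with open(records_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _RECORD_COLUMNS if c not in header]
        if missing:
            raise CohortValidationError(
                f"{records_path}: missing columns {missing}"
            )
        records: list[IndividualRecord] = []
        n_excluded = 0
        cohort_treatment = treatment
        for i, row in enumerate(reader, start=2):
            where = f"{records_path}:{i}"
            row_treatment = row["treatment"].strip()
            if cohort_treatment is None:
                cohort_treatment = row_treatment
            if row_treatment != cohort_treatment:
                raise CohortValidationError(
                    f"{where}: treatment {row_treatment!r} does not match "
                    f"{cohort_treatment!r}"
                )
            if row["excluded"].strip() in ("1", "true", "True"):
                n_excluded += 1
                continue
            durations: dict[str, float] = {}
            for stage in PREADULT_STAGES:
                d = _parse_duration(row[f"{stage}_d"], where)
                if d is None:
                    break
                durations[stage] = d
            sex = row["sex"].strip() or "U"
            adult_d = _parse_duration(row["adult_d"], where)
            records.append(
                IndividualRecord(
                    individual_id=row["individual_id"].strip(),
                    treatment=row_treatment,
                    stage_durations=durations,
                    sex=sex,
                    adult_duration=adult_d,
                )
            )
    by_id = {rec.individual_id: rec for rec in records}
    with open(fecundity_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _FECUNDITY_COLUMNS if c not in header]
        if missing:
            raise CohortValidationError(
                f"{fecundity_path}: missing columns {missing}"
            )
        for i, row in enumerate(reader, start=2):
            where = f"{fecundity_path}:{i}"
            ind = row["individual_id"].strip()
            rec = by_id.get(ind)
            if rec is None:
                raise CohortValidationError(
                    f"{where}: fecundity row references unknown individual {ind!r}"
                )
            if rec.sex != "F":
                raise CohortValidationError(
                    f"{where}: fecundity row references non-female individual "
                    f"{ind!r} (sex {rec.sex!r})"
                )
            try:
                age_day = int(row["age_day"])
                eggs = int(row["eggs"])
            except ValueError:
                raise CohortValidationError(
                    f"{where}: age_day and eggs must be integers"
                ) from None
            if eggs > 0:
                rec.daily_fecundity[age_day] = (
                    rec.daily_fecundity.get(age_day, 0) + eggs
                )
    if cohort_treatment is None:
        raise CohortValidationError(f"{records_path}: no rows")
    return Cohort(
        treatment=cohort_treatment,
        records=records,
        initial_n=len(records) + n_excluded,
    )
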