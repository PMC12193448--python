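"""Bootstrap standard errors and paired bootstrap treatment comparisons.

The resampling unit is the *individual from the full initial cohort* —
never-hatched eggs and pre-adult deaths are resampled jointly with the
adults, so survivorship uncertainty propagates into every statistic.  A
resample in which a statistic is undefined (for instance no reproducing
female, so r has no root) is dropped from that statistic's SE and counted;
a result where more than half the resamples are degenerate is flagged
unreliable.

Randomness is organised as one root seed from which per-statistic,
per-cohort streams are derived deterministically — keyed by the statistic
name and a digest of the cohort's content — so adding a statistic or
reordering treatments does not perturb the others, and the paired test is
bit-identical under exchanging its two cohorts.
"""

from __future__ import annotations

import hashlib
import math
import zlib
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .records import Cohort
from .parameters import estimate_parameters
from . import traits as _traits

__all__ = [
    "BootstrapResult",
    "PairedComparison",
    "bootstrap",
    "paired_bootstrap_test",
    "compact_letters",
    "STATISTICS",
]

_MASK31 = (1 << 31) - 1

Statistic = Callable[[Cohort], float]


def _cohort_digest(cohort: Cohort) -> int:
    """Stable 31-bit digest of a cohort's content (order-independent)."""
    items = sorted(
        (
            rec.individual_id,
            tuple(rec.stage_durations.items()),
            rec.sex,
            rec.adult_duration if rec.adult_duration is not None else -1.0,
            tuple(sorted(rec.daily_fecundity.items())),
        )
        for rec in cohort.records
    )
    payload = repr((cohort.treatment, cohort.initial_n, items)).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") & _MASK31


def _stream(seed: int, statistic_name: str, digest: int) -> np.random.Generator:
    key = zlib.crc32(statistic_name.encode()) & _MASK31
    return np.random.default_rng(
        np.random.SeedSequence([seed & _MASK31, key, digest])
    )


def _resample(cohort: Cohort, idx: np.ndarray) -> Cohort:
    """Build an unvalidated resampled cohort (records are shared, not copied)."""
    new = Cohort.__new__(Cohort)
    new.treatment = cohort.treatment
    new.records = [cohort.records[i] for i in idx]
    new.initial_n = cohort.initial_n
    return new


@dataclass
class BootstrapResult:
    statistic: str
    point: float
    boot_mean: float
    se: float
    B: int
    n_degenerate: int
    seed: int
    unreliable: bool


@dataclass
class PairedComparison:
    statistic: str
    treatment_a: str
    treatment_b: str
    diff: float
    p: float
    alpha: float
    significant: bool
    B: int
    n_degenerate: int


def bootstrap(
    cohort: Cohort,
    statistic: Statistic,
    B: int,
    seed: int,
    name: str | None = None,
) -> BootstrapResult:
    """Bootstrap SE of ``statistic`` over B resamples of the initial cohort."""
    if B < 1:
        raise ValueError("B must be >= 1")
    name = name or getattr(statistic, "__name__", "statistic")
    point = statistic(cohort)
    if not math.isfinite(point):
        raise ValueError(f"statistic {name!r} is not estimable on the point cohort")
    n = len(cohort.records)
    rng = _stream(seed, name, _cohort_digest(cohort))
    idx = rng.integers(0, n, size=(B, n))
    values = np.empty(B)
    for b in range(B):
        values[b] = statistic(_resample(cohort, idx[b]))
    ok = np.isfinite(values)
    n_degenerate = int(B - ok.sum())
    kept = values[ok]
    boot_mean = float(kept.mean()) if kept.size else math.nan
    se = float(kept.std(ddof=1)) if kept.size > 1 else (0.0 if B == 1 else math.nan)
    return BootstrapResult(
        statistic=name,
        point=point,
        boot_mean=boot_mean,
        se=se,
        B=B,
        n_degenerate=n_degenerate,
        seed=seed,
        unreliable=n_degenerate > B / 2,
    )


def paired_bootstrap_test(
    cohort_a: Cohort,
    cohort_b: Cohort,
    statistic: Statistic,
    B: int,
    seed: int,
    alpha: float = 0.05,
    name: str | None = None,
) -> PairedComparison:
    """Two-sided paired bootstrap test of a statistic between two cohorts.

    Draws B paired resamples (one per cohort, independent streams), forms
    the difference distribution Δ* = θ*_A − θ*_B, and returns the two-sided
    percentile p-value 2·min(Pr(Δ* ≤ 0), Pr(Δ* ≥ 0)) clipped to [0, 1].
    Resample pairs where either side is degenerate are dropped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    name = name or getattr(statistic, "__name__", "statistic")
    point_a = statistic(cohort_a)
    point_b = statistic(cohort_b)
    if not (math.isfinite(point_a) and math.isfinite(point_b)):
        raise ValueError(f"statistic {name!r} not estimable on both point cohorts")
    rng_a = _stream(seed, name, _cohort_digest(cohort_a))
    rng_b = _stream(seed, name, _cohort_digest(cohort_b))
    na, nb = len(cohort_a.records), len(cohort_b.records)
    idx_a = rng_a.integers(0, na, size=(B, na))
    idx_b = rng_b.integers(0, nb, size=(B, nb))
    deltas = np.empty(B)
    for b in range(B):
        va = statistic(_resample(cohort_a, idx_a[b]))
        vb = statistic(_resample(cohort_b, idx_b[b]))
        deltas[b] = va - vb
    ok = np.isfinite(deltas)
    n_degenerate = int(B - ok.sum())
    kept = deltas[ok]
    if kept.size == 0:
        p = math.nan
    else:
        p_lo = float(np.mean(kept <= 0))
        p_hi = float(np.mean(kept >= 0))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    return PairedComparison(
        statistic=name,
        treatment_a=cohort_a.treatment,
        treatment_b=cohort_b.treatment,
        diff=point_a - point_b,
        p=p,
        alpha=alpha,
        significant=bool(p < alpha) if math.isfinite(p) else False,
        B=B,
        n_degenerate=n_degenerate,
    )


def compact_letters(
    means: Mapping[str, float],
    significant: Mapping[frozenset, bool] | Callable[[str, str], bool],
    descending: bool = True,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Treatments are ranked by mean (descending by default) and letters
    assigned so that two treatments share at least one letter if and only
    if they are not significantly different.  Non-transitive patterns come
    out as multi-letter labels (e.g. ``"ab"``), never dropped.
    """
    if callable(significant):
        sig = significant
    else:
        table = dict(significant)

        def sig(a: str, b: str) -> bool:
            return bool(table[frozenset((a, b))])

    order = sorted(means, key=lambda k: means[k], reverse=descending)
    rank = {t: i for i, t in enumerate(order)}
    columns: list[frozenset] = [frozenset(order)]
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if not sig(a, b):
                continue
            new_columns: list[frozenset] = []
            for col in columns:
                if a in col and b in col:
                    new_columns.append(col - {a})
                    new_columns.append(col - {b})
                else:
                    new_columns.append(col)
            # absorb: drop empty sets and sets contained in another
            new_columns = [c for c in set(new_columns) if c]
            columns = [
                c
                for c in new_columns
                if not any(c < other for other in new_columns)
            ]
    columns.sort(key=lambda col: tuple(sorted(rank[t] for t in col)))
    labels = {t: "" for t in order}
    for letter_idx, col in enumerate(columns):
        letter = chr(ord("a") + letter_idx)
        for t in order:
            if t in col:
                labels[t] += letter
    return labels


# --------------------------------------------------------------------------
# Statistic functionals on cohorts, usable as bootstrap targets.

def _param_stat(key: str) -> Statistic:
    def stat(cohort: Cohort) -> float:
        return estimate_parameters(cohort).as_dict()[key]

    stat.__name__ = key
    return stat


def _fecundity(cohort: Cohort) -> float:
    females = cohort.females()
    if not females:
        return math.nan
    return sum(sum(r.daily_fecundity.values()) for r in females) / len(females)


def _preadult_survival(cohort: Cohort) -> float:
    return _traits.preadult_survival(cohort)


def _sex_ratio(cohort: Cohort) -> float:
    return _traits.sex_ratio(cohort)


def _mean_lifespan(cohort: Cohort) -> float:
    return sum(r.death_age for r in cohort.records) / len(cohort.records)


def _trait_mean(fn: Callable[[Cohort], dict], key: str, name: str) -> Statistic:
    def stat(cohort: Cohort) -> float:
        try:
            return fn(cohort)[key].mean
        except (ValueError, KeyError):
            return math.nan

    stat.__name__ = name
    return stat


#: Named statistic functionals: Cohort -> float (NaN when not estimable).
STATISTICS: dict[str, Statistic] = {
    "R0": _param_stat("R0"),
    "r": _param_stat("r"),
    "lambda": _param_stat("lambda"),
    "T": _param_stat("T"),
    "fecundity": _fecundity,
    "preadult_survival": _preadult_survival,
    "sex_ratio": _sex_ratio,
    "mean_lifespan": _mean_lifespan,
    "APOP": _trait_mean(_traits.oviposition_stats, "APOP", "APOP"),
    "TPOP": _trait_mean(_traits.oviposition_stats, "TPOP", "TPOP"),
    "oviposition_days": _trait_mean(
        _traits.oviposition_stats, "oviposition_days", "oviposition_days"
    ),
}
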