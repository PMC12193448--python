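"""Population growth parameters from the age schedules.

Four parameters summarise a cohort's demography:

* net reproductive rate  R0 = Σ_x l_x m_x           (offspring / newborn)
* intrinsic rate          r : Σ_x e^{-r(x+1)} l_x m_x = 1   (per day)
* finite rate             λ = e^r                    (per day)
* mean generation time    T = ln(R0) / r             (days)

The Euler–Lotka equation is solved with the age-indexing convention that
reproduction at age x is discounted by exponent (x + 1); this is the
convention under which λ = e^r and the newborn reproductive-value identity
v_{0,egg} = λ hold simultaneously on the daily grid.

A cohort in which no female ever reproduces (e.g. one whose eggs never
hatched) has R0 = 0 and no finite growth-rate solution; r, λ and T are then
flagged not estimable rather than raised, so bootstrap resamples that
happen to contain no reproducing female remain handleable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .lifetable import AgeSchedule, age_schedules, build_schedule
from .records import Cohort

__all__ = [
    "DemographicParameters",
    "NotEstimableError",
    "net_reproductive_rate",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "estimate_parameters",
    "euler_lotka_residual",
]

#: Fixed bisection bracket for r (per day); covers every biologically
#: plausible arthropod growth rate by a wide margin.
R_BRACKET = (-2.0, 2.0)
R_XTOL = 1e-12
RESIDUAL_TOL = 1e-9


class NotEstimableError(ValueError):
    """A growth parameter has no defined value for this cohort."""


@dataclass
class DemographicParameters:
    """Point estimates of R0, r, λ, T with per-parameter estimability."""

    R0: float
    r: float | None
    lam: float | None
    T: float | None

    @property
    def estimable(self) -> dict[str, bool]:
        return {
            "R0": True,
            "r": self.r is not None,
            "lambda": self.lam is not None,
            "T": self.T is not None,
        }

    def as_dict(self) -> dict[str, float]:
        nan = float("nan")
        return {
            "R0": self.R0,
            "r": self.r if self.r is not None else nan,
            "lambda": self.lam if self.lam is not None else nan,
            "T": self.T if self.T is not None else nan,
        }


def net_reproductive_rate(ages: AgeSchedule) -> float:
    """R0 = Σ_x l_x m_x; equals (total eggs laid)/(initial egg count)."""
    return float(np.sum(ages.lxmx))


def euler_lotka_residual(r: float, lxmx: np.ndarray) -> float:
    """Σ_x e^{-r(x+1)} l_x m_x − 1; strictly decreasing in r."""
    x = np.arange(len(lxmx), dtype=float)
    return float(np.sum(np.exp(-r * (x + 1)) * lxmx) - 1.0)


def intrinsic_rate(ages: AgeSchedule) -> float:
    """Solve the Euler–Lotka equation for r by bracketed bisection.

    The residual is monotone decreasing in r, so the root in the fixed
    bracket is unique.  Raises NotEstimableError when R0 = 0 and a plain
    ValueError when the bracket shows no sign change (R0 pathologically
    far from 1, outside any biological regime).
    """
    lxmx = np.asarray(ages.lxmx, dtype=float)
    if net_reproductive_rate(ages) <= 0:
        raise NotEstimableError("R0 = 0: no reproduction, r undefined")
    lo, hi = R_BRACKET
    f_lo = euler_lotka_residual(lo, lxmx)
    f_hi = euler_lotka_residual(hi, lxmx)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            f"no sign change on bracket {R_BRACKET}: "
            f"residual({lo})={f_lo:.3g}, residual({hi})={f_hi:.3g}"
        )
    root = float(bisect(euler_lotka_residual, lo, hi, args=(lxmx,), xtol=R_XTOL))
    if abs(euler_lotka_residual(root, lxmx)) >= RESIDUAL_TOL:
        raise RuntimeError("Euler–Lotka residual above tolerance after bisection")
    return root


def finite_rate(r: float) -> float:
    """λ = e^r (per-day population multiplication factor)."""
    return math.exp(r)


def mean_generation_time(R0: float, r: float) -> float:
    """T = ln(R0)/r, the time to grow R0-fold at the stable distribution."""
    if R0 <= 0:
        raise NotEstimableError("T undefined for R0 <= 0")
    if r == 0:
        raise NotEstimableError("T undefined for r = 0")
    return math.log(R0) / r


def estimate_parameters(cohort: Cohort) -> DemographicParameters:
    """Full pipeline: cohort → schedules → (R0, r, λ, T) with flags."""
    ages = age_schedules(build_schedule(cohort))
    R0 = net_reproductive_rate(ages)
    try:
        r = intrinsic_rate(ages)
    except NotEstimableError:
        return DemographicParameters(R0=R0, r=None, lam=None, T=None)
    lam = finite_rate(r)
    try:
        T = mean_generation_time(R0, r)
    except NotEstimableError:
        T = None
    return DemographicParameters(R0=R0, r=r, lam=lam, T=T)
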