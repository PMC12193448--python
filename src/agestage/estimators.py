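"""Fit-style estimator facades over the life-table pipeline.

`AgeStageLifeTable` follows the scikit-learn estimator protocol (``fit``
returning ``self``, fitted attributes with a trailing underscore,
``get_params``/``set_params``) so it drops into code written around that
convention; the input is a :class:`~agestage.records.Cohort` rather than a
feature matrix, so sklearn ``Pipeline`` composition does not apply.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .bootstrap import STATISTICS, bootstrap, compact_letters, paired_bootstrap_test
from .lifetable import age_schedules, build_schedule, life_expectancy, reproductive_value
from .records import Cohort
from .parameters import (
    finite_rate,
    intrinsic_rate,
    mean_generation_time,
    net_reproductive_rate,
    NotEstimableError,
)
from .traits import trait_table

__all__ = ["AgeStageLifeTable", "BootstrapComparison"]


class AgeStageLifeTable(BaseEstimator):
    """Age-stage, two-sex life table fitted to one cohort.

    Parameters
    ----------
    compute_stage_matrices : bool, default True
        Also compute the age-stage life expectancy (``expectancy_``) and,
        when r is estimable, reproductive value (``reproductive_value_``).

    Attributes (after ``fit``)
    --------------------------
    schedule_ : AgeStageSchedule   s_xj / f_xj matrices
    ages_ : AgeSchedule            l_x, m_x, l_x m_x
    R0_, r_, lambda_, T_ : float or None
    expectancy_, reproductive_value_ : ndarray or None
    traits_ : DataFrame            trait means, SEs and ns
    """

    def __init__(self, compute_stage_matrices: bool = True):
        self.compute_stage_matrices = compute_stage_matrices

    def fit(self, cohort: Cohort, y=None) -> "AgeStageLifeTable":
        if not isinstance(cohort, Cohort):
            raise TypeError("AgeStageLifeTable.fit expects a Cohort")
        self.treatment_ = cohort.treatment
        self.schedule_ = build_schedule(cohort)
        self.ages_ = age_schedules(self.schedule_)
        self.R0_ = net_reproductive_rate(self.ages_)
        try:
            self.r_ = intrinsic_rate(self.ages_)
            self.lambda_ = finite_rate(self.r_)
        except NotEstimableError:
            self.r_ = None
            self.lambda_ = None
        try:
            self.T_ = (
                mean_generation_time(self.R0_, self.r_)
                if self.r_ is not None
                else None
            )
        except NotEstimableError:
            self.T_ = None
        self.expectancy_ = None
        self.reproductive_value_ = None
        if self.compute_stage_matrices:
            self.expectancy_ = life_expectancy(self.schedule_)
            if self.r_ is not None:
                self.reproductive_value_ = reproductive_value(self.schedule_, self.r_)
        self.traits_ = trait_table(cohort)
        return self

    def summary(self) -> dict:
        """Fitted demographic parameters as a plain dict."""
        return {
            "treatment": self.treatment_,
            "R0": self.R0_,
            "r": self.r_,
            "lambda": self.lambda_,
            "T": self.T_,
        }


class BootstrapComparison(BaseEstimator):
    """Bootstrap SEs and all-pairs paired bootstrap tests across cohorts.

    Parameters
    ----------
    statistics : sequence of str
        Names from :data:`agestage.bootstrap.STATISTICS`.
    B : int
        Bootstrap iterations.
    seed : int
        Root seed; all streams derive from it.
    alpha : float
        Per-pair significance level.

    Attributes (after ``fit``)
    --------------------------
    results_ : {statistic: {treatment: BootstrapResult}}
    comparisons_ : list[PairedComparison]
    letters_ : {statistic: {treatment: str}}  compact letter displays
    """

    def __init__(self, statistics=("R0", "r", "lambda", "T"), B: int = 100_000,
                 seed: int = 0, alpha: float = 0.05):
        self.statistics = statistics
        self.B = B
        self.seed = seed
        self.alpha = alpha

    def fit(self, cohorts: list[Cohort], y=None) -> "BootstrapComparison":
        import math

        self.results_ = {}
        self.comparisons_ = []
        self.letters_ = {}
        for name in self.statistics:
            stat = STATISTICS[name]
            per_treatment = {}
            points = {}
            for cohort in cohorts:
                value = stat(cohort)
                if math.isfinite(value):
                    per_treatment[cohort.treatment] = bootstrap(
                        cohort, stat, self.B, self.seed, name=name
                    )
                    points[cohort.treatment] = value
            self.results_[name] = per_treatment
            estimable = [c for c in cohorts if c.treatment in points]
            sig: dict[frozenset, bool] = {}
            for i, ca in enumerate(estimable):
                for cb in estimable[i + 1 :]:
                    cmp_ = paired_bootstrap_test(
                        ca, cb, stat, self.B, self.seed, alpha=self.alpha, name=name
                    )
                    self.comparisons_.append(cmp_)
                    sig[frozenset((ca.treatment, cb.treatment))] = cmp_.significant
            if len(points) >= 2:
                self.letters_[name] = compact_letters(points, sig)
            elif points:
                self.letters_[name] = {next(iter(points)): "a"}
            else:
                self.letters_[name] = {}
        return self
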