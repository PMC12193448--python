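# Methods

## Scope and data model

The package analyses single-cohort life-table experiments on arthropods
with the stage sequence egg → larva → protonymph → deutonymph → adult
(female/male), development checked every 12 h and survival/fecundity
recorded daily. A record is one individual: a *prefix* of stage durations
on the 0.5-day census grid (the last entry being time survived in the
stage of death), sex (`U` for pre-adult deaths), adult duration, and a map
from whole-day age to eggs laid. The cohort's `initial_n` — the number of
eggs started — is stored separately from the record list: it is the
denominator of every per-newborn rate, and an explicit `excluded` marker
lets individuals lost to handling count in `initial_n` without
contributing data. Without exclusions, `initial_n` must equal the record
count; the analysis does not silently absorb missing individuals.

Fecundity ages are validated to lie in `[pre-adult duration, death age)`.
The upper bound is strict: with half-up rounding to the daily grid, an egg
recorded at an age equal to an integer death age would fall on a day the
female is already counted dead, and the exact maternity identity below
would fail. Under 12-h censusing the last possible laying observation
precedes death, so the strict bound encodes the measurement process.

## From half-days to the daily grid

Censuses are half-daily; the life table is daily. Ages map to day classes
by rounding half-up (`day_index`: 1.5 → 2), and an individual dying at age
D occupies days 0 … day_index(D) − 1. Cumulative rounded stage boundaries
assign each alive day to exactly one stage; on a day when a moult falls
the individual belongs to the *later* stage (transition at the start of
the rounded day). The convention is arbitrary where the source material is
silent; fixing it makes the hand-enumerated oracles in the test suite
reproducible. Trait statistics (stage durations, longevities, APOP) use
the raw half-day values; only the schedules and everything derived from
them use the daily grid.

## Schedules and parameters

`s_xj` is the occupancy count at (x, j) over `initial_n`; `f_{x,female}`
is total eggs laid at age x divided by females alive at x. Because every
valid laying day falls inside the layer's female-adult occupancy window,

    Σ_x l_x m_x = Σ_x Σ_j s_xj f_xj = (total eggs laid) / initial_n

holds exactly on every cohort, which also gives the count identity
R0 = mean fecundity × (females / initial_n) used throughout.

`e_xj` and `v_xj` are computed by backward recursion on the cohort's
empirical day-to-day stage-transition frequencies (the conditional
occupancy construction of the framework): e_xj = 1 + Σ_y P_x[j,y] e_{x+1,y}
(the current day counts), and v_xj is the analogous recursion on the
discounted fecundity stream e^{−r(i+1)} f_iy, rescaled by e^{r(x+1)}.
Entries at never-occupied (x, j) are NaN, not 0 — zero is a meaningful
reproductive value. Two consequences serve as internal checks: e_{0,egg}
equals the mean (rounded) lifespan over all individuals, and
v_{0,egg} = λ at the Euler–Lotka root (exact when there are no excluded
individuals; with k exclusions it scales by N/(N−k)).

The intrinsic rate solves Σ e^{−r(x+1)} l_x m_x = 1 by bisection on the
fixed bracket [−2, 2] d⁻¹ (xtol 1e−12, residual asserted < 1e−9). The
residual is strictly decreasing in r, so the root is unique; the bracket
covers any biologically plausible rate and bisection is preferred over
Newton for unconditional convergence at this problem size. The (x+1)
discount exponent is the convention under which λ = e^r and the
newborn-value identity hold simultaneously on a grid that starts at age 0.
R0 = 0 (no reproduction) flags r, λ and T not estimable instead of
raising, so degenerate bootstrap resamples are representable.

## Bootstrap inference

The resampling unit is the individual drawn with replacement from the full
initial cohort, so survivorship and trait uncertainty propagate jointly.
SE is the SD (ddof 1) of the estimable replicates; replicates where the
statistic is undefined are dropped and counted, and a result with > 50%
degenerate replicates is flagged unreliable. The paired test draws B
independent resample pairs and uses the two-sided percentile p-value
2·min(Pr(Δ* ≤ 0), Pr(Δ* ≥ 0)), clipped to [0, 1]; the source material
names the test without a formula, and this is the standard symmetric
percentile form. B defaults to 100,000 (the published setting) and is a
parameter everywhere; tests and examples use reduced B.

RNG streams derive from one root seed, keyed by statistic name and a
SHA-256 digest of each cohort's content. Consequences: adding a statistic
or reordering treatments perturbs nothing else; exchanging the two cohorts
of a paired test flips every Δ* sign exactly, so p is bit-identical; two
distinct cohorts from the same generator still get independent streams;
and testing a cohort against itself gives Δ* ≡ 0, p = 1.

Compact letter displays use insert-and-absorb: treatments sorted by mean
(descending), each significant pair splits every column containing both,
subset columns are absorbed, and letters are assigned in rank order. Two
treatments share a letter iff they are not significantly different;
non-transitive patterns yield multi-letter labels. No multiple-testing
correction is applied beyond the per-pair α = 0.05, matching the source
analysis.

## Synthetic cohorts

Presets `control`, `t36`, `t38`, `t40`, `t42` encode the four-temperature
heat-stress design (50-egg cohorts, 4-h exposure at the egg stage). Per
egg: hatch Bernoulli; per-stage survival Bernoullis with probabilities
apportioned from the published per-stage sample sizes (e.g. control
50 → 49 → 47 → 37 → 33, giving pre-adult survival exactly 0.66); stage
durations, adult durations, APOP, oviposition days and lifetime fecundity
as normals truncated at 0 with SD = SE·√n backed out of the published
SEs, discretised to the census grid where applicable; sex Bernoulli at
adulthood (e.g. 24/33 female for the control); laying days placed from the
first oviposition day with a triangular daily profile peaking at the
treatment's observed peak fecundity age (days 23/18/18/16), egg counts
multinomial so the lifetime total is hit exactly. `t42` has hatch
probability 0; its egg "duration" is the survival time of the unhatched
egg under observation.

What the generator does *not* emulate, and hence what recovery tests do
not show about real data: between-trait correlations (a long-lived female
is not made more fecund beyond the structural constraint that laying fits
inside her adult span), within-stage death timing (deaths are placed at
the end of a full drawn stage duration — the failed moult — because
census data cannot localise them further), temperature as a continuous
covariate (presets are per-treatment lookups, not a thermal-performance
curve), and any dispersion structure beyond first and second moments.
Recovery tests therefore target the generator's own configured
parameters, not the published SEs. The realised intrinsic rate of a
simulated cohort is consequently somewhat lower than the published r
(the triangular profile places more reproduction late), which is why the
acceptance checks for r-derived quantities run on published inputs rather
than simulated cohorts.

`reconstruct_cohort` builds a *deterministic synthetic* cohort whose
marginal counts (stage completers, adult sex counts, total eggs — rounded
from the calibration chain) match the published tables exactly, with
nominal fixed durations. It exists to exercise the exact count identities
(R0 = F·N_f/N, survival and sex-ratio proportions) through the full
pipeline; it is a stand-in for the undeposited raw records, not an
estimate of them.

## Problem sizes and numerical choices

Unit and property tests run cohorts of 30–80 eggs; large-sample recovery
uses n = 5,000 (Monte-Carlo SE on mean fecundity ≈ 0.14 egg, on survival
≈ 0.007); bootstrap calibration uses B = 50,000 against the closed-form
s/√n, and the paired-test type-I check runs 500 null replicates at
B = 2,000 — sizes chosen to keep sampling error an order of magnitude
below the tolerances being asserted while the whole suite runs in about a
minute. Ties in the compact-letter column ordering break on the sorted
rank tuple; truncated normals are sampled by rejection (acceptance > 0.97
for every preset parameter); durations discretise to the grid with a
0.5-day floor.

## Known limitations

- Stage occupancy conventions (half-up rounding, later-stage assignment on
  moult days) are one defensible reading of 12-h census data; alternative
  conventions shift schedules by at most one day class.
- The two-sex framework's female-fecundity attribution is retained: males
  contribute survival structure only.
- Bootstrap p-values at B iterations have resolution 2/B; letter displays
  inherit that granularity.
- With excluded individuals the v_{0,egg} = λ identity holds only up to
  the factor N/(N−k); no published treatment requires exclusions.
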