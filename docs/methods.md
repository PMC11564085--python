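# Methods

This note documents the model, the parameter choices, what the synthetic
world does and does not emulate, and the numerical decisions — the things
a maintainer would want to know before trusting or changing a number.

## Model overview

The pipeline runs in three steps.

1. **Frontier estimation.** The mortality frontier is the lowest-achieved
   mortality profile: per age group, cause and year, the 10th percentile
   of death rates across eligible countries. Eligibility (population ≥ 5
   million in the 2019 reference year, income data available, high-quality
   vital registration, estimates present) screens out the small and
   poorly-measured populations whose lowest recorded rates are mostly
   noise; the 10th percentile rather than the minimum guards against
   implausibly low cause assignment in individual countries. Frontiers are
   pooled across sexes — each eligible country contributes one pool value
   per sex — except breast and cervix uteri cancer, which get
   female-specific frontiers and a structural male zero.

2. **Trajectory projection.** Each cell's series is fitted by OLS of
   log(rate) on calendar year over 2000–2019 and evaluated as
   rate(t) = exp(b₀ + b₁(t − 2000)) through 2050. The same treatment is
   applied to every country–sex–age–cause series; country projections are
   population-weighted into six regions.

3. **Valuation.** Rates become annual probabilities of dying under a
   constant hazard, q = 1 − e^(−m); the avoidable gap is
   δ = max(q_C − q_F, 0). The value of closing δ is anchored to the VSL,
   extrapolated across incomes with a piecewise elasticity and floored,
   age-adjusted by discounted remaining life expectancy, and passed
   through a concave value function bounded by income. Results are
   reported as % of annual income.

## Nested level-wise rescaling

Percentiles are not additive, so raw cause frontiers do not sum to the
all-cause frontier. Consistency is restored top-down: level-1 siblings are
multiplied by `target / Σ siblings` within each cell, then each level-2
sibling set is scaled to its already-rescaled parent, then level 3. The
procedure is idempotent and conserves the parent at every level to within
1e-9 relative tolerance (asserted in the suite). Two degenerate rules: a
zero sibling sum under a zero target is a no-op (factor 1), and a zero
sibling sum under a positive target is an error ("unattributable mass") —
mass cannot be invented for causes that have none.

**Sex handling.** The frontier surface is sexless except for the two
female-specific cancers. When a sexless parent's sibling sum includes a
sex-split child, the child contributes its **female** value, and the
resulting factor applies to both of its sex rows (the male row stays 0).
Rationale: the frontier is the profile of a reference population in which
female-specific cancers do occur; using the male (zero) branch would let
the remaining siblings absorb breast/cervix mass that the frontier
actually attributes to those cancers. The source publications do not state
their convention; this one is documented rather than asserted as theirs.

**Minimum-frontier variant.** The sensitivity frontier replaces the cause
percentile with the cause minimum but keeps the 10th-percentile (or
external) all-cause target — the variant changes the cause profile, not
the all-cause envelope. A consequence worth knowing: after rescaling to a
common target, minimum-based value shares are *not* uniformly larger than
percentile-based shares; branch-specific scale factors can push individual
cells either way, and the observed shifts are small in both directions.

## Valuation choices

* **VSL extrapolation**: VSL_C = R·y_A·(y_C/y_A)^η with anchor ratio
  R = 160 at the anchor economy's GNI per capita y_A, η = 0.8 above /
  1.2 below the anchor income. The floor VSL_C ≥ 20·y_C is applied after
  extrapolation, to the initial VSL/GNI ratio, before any age adjustment.
  Sensitivity scenarios set η = 1.0 or 1.5 on both sides, or R = 100
  anchored at the rich-region mean income.
* **Age adjustment**: VSL\* = VSL_C · DRL(a)/DRL(40), where DRL is
  survival-weighted, discounted (r = 3%/yr; 1% and 5% in sensitivity)
  remaining years of life from the age group's midpoint, computed from the
  region's own all-cause schedule on a single-year grid capped at age 100.
  This gives the discount rate a well-defined role: discounting shortens
  the effective horizon of the *anchor* age more than of old ages, so a
  higher rate raises the relative value of old-age causes (the direction
  the sensitivity scenarios reproduce for cardiovascular disease).
* **Concave value function**: v(δ) = y·(1 − e^(−(VSL\*/y)·δ)). This is the
  minimal form that (i) equals VSL\*·δ in the small-risk limit, (ii) is
  strictly increasing and strictly concave in δ (each further reduction of
  a large risk is worth less), and (iii) is bounded by one year's income,
  matching the metric's reading as income one would forgo. The form is a
  documented stand-in for the companion machinery the publications build
  on; it honors every property they state and is isolated behind
  `value_of_reduction` so an alternative can be swapped in.
* **Clamping**: δ is clamped at 0 by default — a 10th-percentile frontier
  leaves some cells below it, and negative avoidable mortality is not
  meaningful as a valuation input. `clamp_gaps: false` disables it.
* **Aggregation order**: country rates are population-weighted into
  regions first; probabilities, gaps and values are computed at region
  level with region income (population-weighted GNI per capita). The
  anchor economy is the highest-income country at the reference year.
* **Income projection**: GNI per capita is observed through 2021 and
  projected multiplicatively with per-country growth rates where listed,
  else the average of the listed rates (the world-average fallback).

## The synthetic world

The generator produces a world whose statistical structure is exactly the
one the pipeline assumes, so that estimation error is attributable to the
pipeline and not to model misspecification:

* The true frontier declines log-linearly. Slopes vary by age
  (−2.2%/yr in infancy to −0.5%/yr at the oldest ages) but are **shared
  across causes within an age band** — the cause composition of the
  frontier is constant over time. This is deliberate: sums of exponentials
  with different slopes are not exponential, so heterogeneous cause slopes
  would make the log-linear model misspecified at parent levels and no
  exact recovery benchmark would exist. Per-cause slopes can be supplied
  via `frontier_params` when misspecification itself is the object of
  study.
* Country rates are the frontier × a country–cause spread ≥ 1 (exactly 1
  for the ten designated frontier countries, and increasing as income
  falls) × i.i.d. multiplicative lognormal noise (σ = 0.05 by default —
  the year-to-year wobble of national cause-specific rates; recovery is
  additionally exercised at σ ∈ {0, 0.01}). Male rates carry a constant
  ×1.4 excess; breast/cervix male rates are 0.
* Incomes span 900–70,000 (2017 PPP$), wide enough that the VSL floor can
  bind under the high-elasticity scenario (floor binds when
  y_C/y_A < (20/160)² ≈ 1/64 at η = 1.5). Populations range 3M–150M with
  younger pyramids in poorer countries; two countries are flagged
  low-quality vital registration and the smallest fall below the 5M
  eligibility cut.
* Six regions are blocks of 4,4,3,3,3,3 countries ordered by income —
  a high-income block through a low-income block, mirroring the role (not
  the geography) of the regional grouping.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: cause-of-death misclassification and its
geographic drift, mortality shocks (wars, epidemics, earthquakes),
COVID-era disruptions, migration and fertility dynamics, epidemiological
transitions (the synthetic cause mix is constant in time), and reporting
gaps. Recovery results certify the pipeline's correctness under its own
assumptions, not the realism of log-linear extrapolation.

One structural subtlety the null-world test surfaced: with sex-pooled
frontiers, a world containing female-specific cancer mass can never place
*both* sexes on the frontier at cancer-ancestor causes — the pooled
percentile lands on the lower, breast/cervix-free male branch, leaving
female cells above it. The "every country on the frontier" world is
therefore generated sexless (`frontier_world()` zeroes breast/cervix mass
and the male excess); only then is an all-zero value table the correct
expectation.

## Numerical decisions

* **Percentile rule**: linear interpolation between order statistics at
  h = (n−1)p + 1 (numpy's default). With 11 pool values the 10th
  percentile is exactly the 2nd order statistic.
* **OLS**: two-pass centered form (slope = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²),
  vectorized across all cells; agrees with the per-series `np.polyfit`
  path to ~1e-12 and recovers noiseless exponentials to machine precision.
* **Zero-rate years** are excluded from log fits rather than offset by a
  pseudo-count; a series with one positive year projects flat at that
  value, an all-zero series projects zero.
* **Degenerate rescale cells**: factor 1 when child sum and target are
  both zero; error when mass is unattributable.
* **Gap additivity**: gaps add exactly on rates; after the concave
  probability conversion a parent gap differs from the sum of its child
  gaps by a second-order term. The suite asserts agreement within 1% for
  leaf rates below 0.01 and the quadratic shrinkage of the discrepancy as
  rates scale down; at leaf rates near 0.025 worst-case discrepancies of
  ~2% are mathematically attainable and should not be read as bugs.
* **Determinism**: all randomness flows through `numpy.random.default_rng`
  seeded from the config; artifacts are written with a fixed float format
  (`%.10g`), so identical config + inputs give byte-identical outputs. The
  10-digit CSV round-trip bounds cross-run reproducibility of derived
  frontier values at ~1e-9 relative — well inside every stated tolerance,
  but visible if you diff in-memory against re-read values at 1e-12.

## Problem sizes

The reference world is 20 countries × 2 sexes × 19 age groups × 31 causes
over 2000–2050 (~350k observed mortality rows, ~1.2M projected). A full
base run takes ~15 s and the seven-scenario suite ~25 s on one CPU; the
acceptance script completes in a few minutes.

## Known limitations

* The value function and the discounting mechanics are documented
  stand-ins honoring stated properties, not reproductions of unpublished
  companion machinery; absolute share levels on real data would inherit
  that choice (relative orderings are much less sensitive — the point the
  sensitivity grid makes).
* Shares divide by same-year GNI per capita; a reference-year convention
  would shift levels for fast-growing regions.
* No probabilistic forecasting: projections are point extrapolations, and
  no uncertainty intervals are produced by design.
* Morbidity, intervention costs, financial-risk protection and
  socioeconomic disaggregation are out of scope.
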