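# Methods

## The estimation problem

Each observation compares the mean carbon stock of a harvested stand
(X̄_T, Mg C ha⁻¹) with that of an uncut reference stand (X̄_C) for one
carbon pool at one time since the most recent cut.  Reference stands are
old forests or stands unmanaged for more than 80 years; chronosequences
without a contemporaneous control use their oldest stand as the reference
and are tagged `unmanaged_80plus`.  The effect size is the log response
ratio RR = ln(X̄_T/X̄_C), which is symmetric in the two arms, scale-free,
and additive over multiplicative effects.  Its sampling variance follows
the delta method: SE(RR)² = SE_T²/X̄_T² + SE_C²/X̄_C², i.e. the sum of the
arms' squared coefficients of variation.  Results are displayed as percent
differences (e^RR − 1)·100, bounded below by −100 %.

Biomass reported by source studies converts to carbon by a fixed fraction
(default 0.5).  Diameter-based biomass uses a generic power-law allometry
evaluator Σ_c a_c·dbh^(b_c) with caller-supplied coefficients; no species
coefficient tables are bundled and missing coefficients are an error, never
a silent default.

### Zero treatment means

A clearcut measured in its first year can hold zero live-tree carbon.
ln(0) is undefined, so these rows carry `defined = False`, display as
−100 %, and are excluded from every log-scale fit.  No offset constant is
added: any offset would silently shift every weighted estimate, whereas
exclusion only discards observations that carry no within-stand contrast
information on the log scale.  Binned time profiles report such rows as
−100 % display values and count them per bin.

## Heterogeneity partitioning

For effects y_i with weights w_i (1/SE² on the weighted track, unit
weights on the unweighted one):

    Q_total  = Σ w_i (y_i − ȳ_w)²
    Q_within = Σ_g Σ_{i∈g} w_i (y_i − ȳ_g)²
    Q_between = Q_total − Q_within,  tested against χ²(G − 1).

The hierarchical moderator selection tests every candidate at a node,
splits on the candidate with the largest significant Q_between
(α = 0.05), and recurses per level until no candidate is significant or a
subgroup falls below the minimum size (default 3).  Ties break by a fixed
candidate order (pool, treatment, time class, biome, reference type), so
the tree is deterministic.  Time enters as a categorical variable via
configurable decade bins [0, 10), [10, 20), …

Both weight modes run through the same formulas.  A known property of the
inverse-variance Q test is anticonservatism when residual between-study
heterogeneity τ² > 0 is ignored by the weights; the structure-recovery
calibration therefore uses homogeneous within-stratum truths, and real
analyses should read borderline Q_between p-values with that caveat.

## Random-effects pooling and meta-regression

The weighted track models y_i ~ N(x_i'β, se_i² + τ² + Σ_g σ_g²) with
variance components for grouping factors (biome, time class, optionally
study).  τ² is estimated by REML — the restricted likelihood is maximised
over the variance components by L-BFGS-B with the fixed effects profiled
out by GLS — or by the closed-form DerSimonian–Laird moment estimator;
REML falls back to DL with a warning on non-convergence.  Wald intervals
use normal quantiles.  Fixed effects are dummy-coded level-vs-reference
contrasts, or per-level cell means on request.  Cross-checks in the test
suite pin the pooled mean, its SE and τ² to values computed independently
with a reference meta-analysis implementation (agreement ≤ 2·10⁻⁵), and
the unweighted mixed-model track to an independent linear-mixed-model
implementation.

The unweighted track fits the same fixed/random structure with a free
residual variance σ² and unit weights, and includes a study random
intercept by default (multiple observations per study violate
independence); the weighted track leaves the study term off by default.
Uncertainty on the unweighted track comes from non-parametric case
bootstrap: whole studies are resampled with replacement (preserving
within-study correlation), the statistic is recomputed per replicate, and
percentile intervals are reported.  Failed replicates are dropped and
counted; more than 10 % failures warns, total failure raises.

Per-stratum (pool × treatment × biome) summaries report the stratum mean
log-RR with a study-bootstrap percentile CI on the unweighted track, and
REML pooling with a Wald CI on the weighted track.  Back-transformation to
percent differences is applied to pooled estimates and interval endpoints
only, never to individual effects before pooling — averaging percent
differences estimates a different (Jensen-inflated) quantity, and a test
guards against regressions toward it.  Mixed-model stratum fits with a
time-class random term are available through `fit_meta_regression`, but
they are not re-fit inside each bootstrap replicate (cost), and with
strongly treatment-dependent trajectories a shared time random effect can
transfer one treatment's early-time deficit onto the other's cell mean —
the stratum tables therefore stay with the model-free stratum mean.

## Time trends

Trajectories of RR against continuous time since treatment are fitted per
harvest treatment by (weighted) least squares in three families: linear,
single cubic polynomial, and restricted (natural) cubic spline with
interior knots at the 0.25/0.5/0.75 time quantiles.  Weights should be
meta-analytic, 1/(se² + τ̂²), with τ̂² from a preliminary pooling —
raw 1/se² weights let a few ultra-precise points dominate and turn
residual heterogeneity into spurious curvature.

Model selection filters candidates by significance, then picks the lowest
AICc.  Significance follows the hierarchy principle: a family counts as
significant only if the terms it adds beyond the largest simpler candidate
nested within it pass a joint F-test at α (a cubic must justify t² and t³,
not ride on its linear part).  This bounds the probability of spuriously
preferring the cubic under a linear truth at about the test size, which
plain AIC comparison (≈ 13 % asymptotically) does not.  AICc rather than
AIC is the default criterion because the per-treatment subsets fitted here
hold a few dozen to ~100 effects; plain AIC is available.  If no candidate
survives the filter, the intercept-only fit is returned with a diagnostic.
Predictions are clamped to the fitted time range (no extrapolation) and
back-transform above −100 % automatically because fitting happens on the
log scale.

## The synthetic-data generator

The generator encodes the compiled database's structure as its defaults:

* 61 studies with 4–14 observations each (≈ 550 rows); each study draws a
  biome (boreal 43.1 %), each unit a treatment (partial cuts 10.3 % of
  boreal and 20.6 % of temperate rows) and pools by the observed shares
  (live trees 25.4 %, forest floor 20.1 %, coarse woody debris 19.2 %,
  snags 15.3 %, mineral soil 11.4 %, understory 8.7 %).
* Time since treatment is lognormal per treatment — clearcut median 15 y
  (truncated at 110), partial median 9 y (truncated at 50) — matching the
  observed medians, quartiles and maxima.
* Reference stocks per pool are uniform within ±40 % of each pool's share
  of a 223.9 Mg C ha⁻¹ ecosystem total (live trees 40.9 %, mineral soil
  33.6 %, forest floor 14.24 %, snags 5.76 %, coarse woody debris 4.74 %,
  understory 0.72 %).
* True stratum effects: live trees follow trajectories — clearcut
  saturating, θ(t) = −5.41·e^(−t/12.8) (−99.6 % at t = 0, crossing the
  partial-cut line near 30 y, near reference by 60 y); partial cuts linear
  from −50 % at t = 0 to −25 % at t = 50 y.  Coarse woody debris is
  U-shaped (quadratic through +136 %/+43 % at t = 0 for clearcut/partial
  with a −68 % trough at 25 y).  Understory is constant at +121 %, snags
  at −63 %/−30 % (clearcut/partial), temperate clearcut forest floor at
  −21 %, everything else null.
* Between-study heterogeneity: a study-level shift b_s ~ N(0, τ²),
  τ = 0.2 by default — moderate heterogeneity, comparable to the stratum
  contrasts it perturbs.  Within-study error is Normal on the arithmetic
  scale with SD = cv·mean (cv = 0.3, truncated at zero) and reported SE =
  SD/√n for n ~ 3–10 replicates; 19 % of rows are stripped of SE and n,
  reproducing the 81 % variance completeness of the compiled data.
* A fifth of studies are "inventory" studies whose unit-occasions record
  live trees, mineral soil and coarse woody debris together at one shared
  time, so total-ecosystem observations can be composed (mirroring the 12
  publications / 46 observations that allow a total-carbon analysis).
* Early clearcut live-tree rows (t < 1 y) are set to X̄_T = 0 to exercise
  the −100 % handling downstream.

What the generator does **not** emulate: correlated effects within a unit
across pools beyond the shared study shift, biome-dependent trajectories,
reference-type confounding beyond a deterministic assignment rule, secular
trends in study quality, or publication bias.  Passing recovery tests
therefore demonstrates that the estimators recover the truths of this
generative model, not that the field database satisfies those assumptions.

## Total-ecosystem carbon

Within each (study, unit, treatment, time) the measured pool stocks are
summed into one total-carbon observation; units missing any required pool
(default: live trees, mineral soil, coarse woody debris) are excluded.
SEs combine as root-sum-of-squares only when every contributing pool
reports one — a partially known variance would understate uncertainty, so
such totals carry no SE and fall to the unweighted track.  At the default
scale only ~12 studies qualify, so this estimate carries visibly more
sampling variance than the pool-level ones.

## Calibration experiments (tests and acceptance script)

* Q machinery: 1,000 random instances against an explicit-loop oracle at
  1e-10; under a homogeneous null with correct weights, mean Q_total
  matches k − 1 within 3 Monte-Carlo SEs over 2,000 replicates (k = 25).
* Hierarchy recovery: 100 replicates of a constructed two-layer truth
  (pool signal ≫ treatment signal; treatment contrast only in aboveground
  pools; mineral soil null, τ = 0 so weights are correctly specified);
  the full structure must be recovered in ≥ 90 %.
* Random-effects recovery: DL τ² exact on 2-study instances; at θ = −0.3,
  τ = 0.2, k = 200, the pooled mean is unbiased within 3 MC SEs and mean
  τ̂² within 25 % of τ² over 500 replicates.
* Bootstrap coverage: nominal 95 % study-bootstrap intervals on the
  generator's null mineral-soil stratum cover zero in 92–98 % of 300
  replicates (n_boot = 500).
* Trend selection: 200 replicates per treatment at k = 100 effects,
  residual τ = 0.15 (heterogeneity about the trajectory, smaller than the
  marginal stratum-level τ), SE ≈ 0.17; the cubic family must win for the
  saturating clearcut truth and the linear family for the linear
  partial-cut truth in ≥ 90 % each, and the median crossing time of the
  two fitted curves must fall in 25–40 y (the generative curves cross at
  ≈ 32 y).

## Numerical choices

* REML optimisation: L-BFGS-B on the variance components with bounds
  [0, 10·var(y)]; σ² floored at 1e-10 on the unweighted track; Cholesky
  factorisation throughout, non-PD proposals rejected with −∞ likelihood.
* CSV I/O uses shortest-roundtrip float formatting on write and exact
  strtod parsing on read, so write → read is bit-identical (pandas' fast
  float parser can be one ulp off).
* Degenerate inputs: identical effects pool to themselves with τ² = 0 and
  a zero-width Q; all-zero SEs are a degenerate-weights error unless all
  effects are identical; a single-level random factor is dropped with a
  warning; rank-deficient designs raise naming the aliased columns.
* All stochastic procedures take explicit integer seeds; identical
  configuration and seed reproduce every output byte-for-byte.

## Known limitations

* The Q partition with inverse-variance weights is anticonservative under
  residual heterogeneity (see above); a τ²-adjusted Q is not provided.
* The weighted meta-regression treats reported SEs as known, as is
  standard; measurement error in the SEs themselves is not modelled.
* Percentile bootstrap intervals undercover slightly when the number of
  studies in a stratum is small (tens); BCa intervals are not implemented.
* Trend fitting per treatment ignores that the same study can contribute
  both treatments; a joint model with study terms across treatments is
  future work.
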