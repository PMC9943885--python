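# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the underlying methodology leaves room.

## Data model

The unit of observation is a *design*: a distinct engineered or evolved
type observed in a calendar year with one positive trait value in
consistent force-like units. Analyses are design-level throughout; the
optional `n_built` production count is carried through but never used as
a weight, because the question is about the space of realized designs,
not production volume. Validation is total — every input row is either
retained or counted in exactly one rejection category (missing/unparsable
field, nonpositive trait, out-of-range year, never-produced flag) — so
the sum of the validation report always equals the input row count.

## Annual summaries

Per year with at least one record: sample size, mean, sample variance
(n−1 denominator; 0 for singleton years), maximum, minimum, quartiles by
linear interpolation (the type-7 convention — stated because quantile
conventions differ), and a modal proxy. The mode of a continuous trait is
estimated as the argmax of a Gaussian kernel density on a 512-point grid
extended three bandwidths past the data range, with the nrd0 rule
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) including its degenerate-spread
fallbacks. Ties break toward the smallest grid point; constant samples
return the constant directly. Because the grid extends past the data, the
reported mode is clipped into [min, max] so summary invariants hold.

Years with zero records are omitted and reported, never interpolated: the
mode likelihoods below handle uneven age spacing natively. Singleton
years get the pooled within-year variance Σ(n_i−1)s_i²/Σ(n_i−1) over all
multi-record years and are flagged; pooling is the standard rescue when a
sampling variance is needed but unobservable.

Only the mean series carries the (mean, variance, n, age) structure the
likelihoods require, so conversion to a fit-ready series rejects any
other statistic. Ages are rebased so the first sample sits at zero.

## Evolutionary-mode models

Four models for a series of sample means x_i with sampling variances
ε_i = v_i/n_i at ages t_i (t_1 = 0):

* **GRW** — general random walk, increments N(μ·Δt, σ²·Δt); parameters
  (anc, μ, σ²), k = 3. The inferred value at the first sample, anc, is a
  free parameter and is counted in k.
* **URW** — μ ≡ 0; (anc, σ²), k = 2.
* **Stasis** — independent N(θ, ω²); k = 2.
* **Strict stasis** — ω² ≡ 0; k = 1. Requires at least one positive ε_i;
  an all-zero sampling variance makes the density singular and the
  log-likelihood is reported as −∞ rather than raised.

**Joint parameterization (default).** The observed means are one
multivariate-normal draw: for the walks, mean anc + μ·t and covariance
σ²·min(t_i, t_j) + δ_ij·ε_i; for stasis, mean θ and covariance
ω²·I + diag(ε). Singular covariances yield −∞.

**AD parameterization.** Successive differences are independent normals:
N(μ·Δt_i, σ²·Δt_i + ε_i + ε_{i+1}) for the walks; for stasis each
non-initial sample contributes N(θ, ω² + ε_i). The AICc sample size is
the number of samples (joint) or of differences (AD). Parameter counts
mirror the joint convention in both methods so AICc values are
comparable across parameterizations.

**Fitting.** For every model the mean-structure parameters (anc, μ, θ)
are exactly solvable by generalized least squares once the single
variance parameter is fixed, so maximization is a one-dimensional profile
likelihood in log-variance: a 60-point log-spaced grid from the variance
floor (10⁻¹⁰, guarding against singular covariances) to three decades
above the data scale, refined by bounded Brent minimization around the
best few grid points. This is deterministic, needs no starting-point
heuristics, and cannot converge to a local optimum in the mean
parameters. Model support uses AICc and Akaike weights; the fit table
prints weights to three decimals.

Selection between URW and GRW is consistent only on average: a realized
driftless walk can wander and legitimately earn directional support
(~15–20% of replicates even asymptotically, since twice the
log-likelihood-ratio is asymptotically χ²₁ under URW). Tests therefore
assert majorities and mean weights, not unanimity.

## Changepoint detection (one-predictor MARS)

With a single predictor (year) the hinge-function model space is the
continuous piecewise-linear functions, so the base model carries an
intercept and a global linear term and each reflected hinge pair
max(0, x−k)/max(0, k−x) contributes one slope change. The pair is kept
despite its collinearity with the linear column; least-squares fits are
computed by `lstsq`, which handles the rank deficiency, and fitted values
are unique even where coefficients are not.

* **Forward pass** — greedily adds the pair minimizing RSS over candidate
  knots (observed years, excluding three observations at each end to
  avoid degenerate hinges; earliest year wins ties), stopping at
  `max_knots` (default 8), at a numerically exact fit, or when no
  candidate improves.
* **Backward pruning** — deletes single basis functions greedily by RSS,
  scoring each path model with GCV = (RSS/n)/(1 − C/n)² where
  C = #coefficients + penalty·#knots (penalty default 2, the
  additive-model convention). Models with C ≥ n are rejected. GCV values
  within float fuzz of the minimum are treated as ties and the smallest
  model wins — necessary because an exact fit has RSS exactly 0 while its
  prunable subsets carry ~10⁻²⁶ rounding residue.
* **Knot-count choice** — k-fold cross-validation (default k = 10). Folds
  are stratified along the time axis (labels permuted within consecutive
  blocks, so every fold samples all eras; contiguous-block folding is
  available by config), drawn from the `mars-cv` seed substream. For each
  knot count the forward/backward passes are re-run on the training
  split and the out-of-fold R² (against the overall-mean baseline) is
  averaged over folds. The retained count is the smallest within 0.01 of
  the maximum — an explicit operationalization of "the R² asymptote".
  The chosen count is refit on all data.

The forward pass alone need not find globally optimal knots (greedy
selection can bracket a true break with two nearby knots); the oracle
equivalence holding after pruning is the designed behavior, and the
noiseless-input tests check exactly that.

Knots convert to phases with the convention that a knot year closes its
phase (phase i ends at knot i; the next phase opens at knot i + 1). Each
phase gets an OLS line of the statistic against year with a t-based 95%
confidence interval on the slope.

## Zone classification

The safe/danger/extinction picture is qualitative; every threshold here
is an explicit, configurable stand-in, echoed in reports:

* **Directional shift** — the first boundary between consecutively fitted
  phases where the best-supported mode switches from
  {URW, stasis, strict stasis} to GRW with μ > 0, accepted only within
  ±5 yr (configurable) of a competitor first-appearance event. The danger
  zone opens at the shift year.
* **Right wall** — the candidate year is the first year the maximum
  series enters a 5%-of-range tolerance band below its global maximum:
  the peak itself for a rise-and-fall ("bounce") series, the plateau
  onset when the series levels off against the wall — a plateau's literal
  argmax lands arbitrarily late, which is why a tolerance band is used.
  The call is accepted when at least 25% of the series follows the
  candidate and the post-candidate OLS slope, including its CI upper
  bound, stays below 0.2% of the series range per year. Plateau noise
  makes the slope's *sign* a coin flip, so the rule bounds the slope
  rather than requiring it negative. The wall year is recorded as
  evidence, not a zone boundary.
* **Left-wall detachment** — the changepoint machinery runs on the
  minimum series (seed substream `mars-cv-min`); the last knot whose
  following phase has a significantly positive slope (95% CI excluding
  zero) opens the extinction zone.

Disturbance events are annotated on reports but never trigger rules,
reflecting the finding that demand shocks perturb these series only
transiently. Degenerate inputs produce a single safe zone with an
explanatory note, and an extinction zone can never appear without a
preceding danger zone by construction.

## Synthetic data

`simulate_mode_series` draws exactly from a chosen mode model plus
sampling noise of variance v/n, recording the true variances and sizes —
the instrument for estimator tests.

`simulate_design_records` emulates the full competitive-exclusion story.
A latent performance frontier walks with standard deviation 0.8/yr —
driftlessly until a competitor's onset year, then with that competitor's
drift added — reflecting off the right wall (reflection, not absorption,
so post-contact maxima can bounce). The feasible lower bound sits at the
left wall until the exclusion onset, then rises linearly. Each year a
Poisson number of designs draws trait values from the band between bound
and frontier — triangular with its peak at 0.6 of the band by default,
placing the mode below the mean as real design populations do (uniform
available for sensitivity checks). Disturbances are 1–3 yr multiplicative
shocks to the design *rate* only: shocks move demand, not trait physics.
If the rising bound would squeeze the band below its minimum width the
frontier is clamped and the year flagged.

Default scenario conditions, chosen once as the validation conditions and
not revisited: 136 years; walls at 1.0 and 100.0 in dimensionless trait
units (every statistic downstream is scale- and unit-free); frontier
starting at 10.0; one competitor in year 60 adding 3.0/yr drift — sized
so the frontier's expected wall contact lands near year 90; exclusion
from year 100 at 1.0/yr; 120 designs per year, matching the density of
the historical record (~16,000 designs over 136 years).

What the generator does *not* emulate: autocorrelated design bursts,
heavy-tailed within-year distributions, measurement error in the trait,
multiple interacting incumbents, or gaps longer than Poisson chance
produces. Passing tests therefore show the pipeline recovers a known
competitive-exclusion signal embedded in realistic year-to-year noise;
they do not show robustness to structured data pathologies.

## Numerical choices and degenerate inputs

* Variance parameters are optimized on a log scale above a 10⁻¹⁰ floor.
* Singular covariances report −∞ likelihoods; fits that never reach a
  finite likelihood are flagged, not raised.
* Constant series with zero sampling variance: stasis recovers θ at the
  constant with ω² at the floor; strict stasis is flagged as singular.
* Phases contributing fewer than 6 sampled years are skipped with a
  recorded reason (the richest model spends 3 parameters; AICc then
  needs n ≥ 5, and 6 leaves one sample of slack).
* All randomness flows from one config seed through named CRC32-keyed
  substreams (`simulation`, `mars-cv`, `mars-cv-min`), so a run is
  bitwise reproducible end to end.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations for a single
core: 200 random series for the likelihood-oracle and nesting checks,
200 replicates for step-variance recovery, 20 replicates per generating
mode for selection consistency, and 50 seeded scenario runs for the
end-to-end recovery rates. These sizes give binomial standard errors
comfortably inside the asserted margins while keeping the whole suite in
the minutes range.

## Known limitations

* The CV fold count (10) needs n ≥ 10 summarized years; shorter series
  cannot use the changepoint stage.
* Knot placement inherits ±2–3 yr jitter from noise near a break, so
  detected shift years carry the same jitter; the zone classifier's ±5 yr
  event window absorbs it.
* AD parameter counts follow the joint convention rather than counting
  only parameters the differenced likelihood identifies; AICc comparisons
  *within* one parameterization are unaffected.
* The right-wall rule presumes the series actually levels or falls after
  contact; a wall reached exactly at the series end is undetectable by
  construction (no post-peak fraction).
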