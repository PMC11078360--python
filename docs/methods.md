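# Methods

## Model

Each subject may carry any of N disease subtypes. Carriage is modelled as
independent Bernoulli(p_n) per subtype per subject (co-carriage allowed, no
competition or facilitation), so the prevalence of the combined condition
is prev_N = 1 − ∏(1 − p_n). Each component test errs independently of other
components and of carriage: positive with probability sens_n given
carriage, with probability 1 − spec_n given none. The panel is positive if
any component is.

Expected component positivity is the linear misclassification map
AP_n = p_n·sens_n + (1 − p_n)(1 − spec_n); the component-level crossover,
where false positives and false negatives balance and positivity equals
prevalence, is p* = (1 − spec)/((1 − spec) + (1 − sens)) — 1.23% at the
default operating point (sens 0.80, spec 0.9975).

At panel level, specificity multiplies (spec_N = ∏ spec_n) while
sensitivity is prevalence-dependent, because component false negatives are
masked by positives elsewhere:

    sens_N = 1 − [∏(1 − AP_n) − spec_N·Q] / (1 − Q),
    Q = ∏ q_n,  q_n = (sens_n − AP_n)/(sens_n + spec_n − 1).

q_n is the component Rogan–Gladen estimate of 1 − p_n; with positivities at
their expected values q_n = 1 − p_n identically. The bias-corrected panel
prevalence estimator

    prev̂_N = [spec_N − (1 − AP_N)]·(1 − Q) / [spec_N − ∏(1 − AP_n)]

is algebraically the Rogan–Gladen correction applied at panel level with
(sens_N, spec_N), and recovers prev_N exactly on expected positivities (the
test suite verifies this to 1e−9 over 1000 random panel configurations).
When a subject-level result matrix is available AP_N is counted directly
(any component positive); the independence product 1 − ∏(1 − AP_n) is used
only when component positivities are the sole input.

Out of scope by design: correlated component errors (e.g. antigenic
cross-reactivity between related serotypes), in-host subtype competition,
and multi-modality testing where several tests target the *same* condition.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| sens_n | 0.80 | component sensitivity (moderately sensitive assay) |
| spec_n | 0.9975 | component specificity (highly specific assay) |
| N | 20 | panel size (serotype panel) |
| prev_N | 0.10 | overall panel prevalence of the packaged scenario |
| n_subjects | 4000 | cohort size of the packaged scenario |
| resampling reps | 1000 | replicate draws per interval |
| MCMC | 32 walkers, 1000+1000 steps | warmup + retained ensemble steps |

The packaged serotype weights are a synthetic stand-in for an invasive
pneumococcal disease case series: each entry is a serotype's share of all
cases, the 20 PCV20 serotypes summing to 0.703 (the remainder being
non-vaccine-type disease, which never enters any computation because only
the relative shape matters). The distribution is constrained to the
documented summary features of such series — a dominant serotype (8) at
25.6% of all cases, a serotype (5) with no observed cases, a long tail in
between, and a maximum component prevalence of 3.8% once scaled to 10%
panel prevalence, leaving serotypes 3 and 8 as the only components above
the 1.23% crossover. Conclusions that depend on the distribution only at
second order (bias ratio, panel crossover) are additionally checked against
uniform weights.

## Simulator

`simulate_cohort` draws subject × component carriage and test-result
matrices. Two child RNG streams (NumPy `SeedSequence.spawn`) are derived
from the root seed — one for carriage, one for test error — so error
realisations can be redrawn with carriage held fixed. Cohorts are
reproducible bit-for-bit given config + seed.

What the generator emulates: independent subtype carriage with a realistic
skewed frequency distribution, independent component misclassification,
nested vaccine-group aggregation. What it does not: correlated errors,
serotype competition, within-population heterogeneity in test performance,
or any feature of real assay chemistry. Passing tests therefore demonstrate
correctness of the estimators *under the stated independence assumptions*,
not robustness to their violation — a confidently mis-specified specificity
prior demonstrably breaks recovery (and a test asserts that it does).

## Uncertainty propagation

Sensitivity and specificity are never estimable from field results alone;
they come from disease-positive and disease-free control groups, encoded as
beta distributions Beta(k + a0, n − k + b0) with uniform pseudo-counts
(a0, b0) = (1, 1) by default.

**Resampling.** Each replicate draws component performance from its prior
and positive counts from a binomial resample of the observed counts, then
applies the component and panel estimators; points are replicate medians,
intervals central quantiles. Replicates with a non-positive Youden index or
a vanishing denominator are dropped and counted (an error is raised above
50% — the panel is underpowered at those operating points); replicates
where every component sits at or below its false positive rate contribute
the zero-prevalence fixed point. Because the panel map is convex in the
resampled inputs, the replicate median sits a few tenths of a percentage
point above the plain estimator at the packaged scenario's size; measured
interval coverage is slightly conservative (~0.99 at nominal 0.95).

**Frequentist.** Single tests use the adjusted estimator of Lang and
Reiczigel: positivity adjusted by +2 successes/+4 trials, Rogan–Gladen
transform with raw control proportions, and a Wald interval whose variance
combines the positivity variance with control-group variances scaled by the
squared Youden index. The panel extension applies the same correction with
(sens_N, spec_N) and a delta-method variance: a numerical gradient of the
panel estimator with respect to every uncertain input (component
positivities, panel positivity, control proportions), inputs treated as
independent. Measured panel coverage at the packaged scenario is ~0.93–0.94
at nominal 0.95. One caveat inherent to Wald-type intervals: when a small
negative-control group is error-free the estimated specificity variance is
zero, and single-test coverage drops to ~0.92 (100 controls at spec
0.9975); with negative-control groups large enough to observe errors (800
at the same specificity) coverage is nominal. The remedy is better test
characterisation, not more subjects.

**Bayesian.** Latent prevalence per component with a uniform prior on
[0, 1]; sensitivity and specificity with informed beta priors; observed
positive counts Binomial(m, prev·sens + (1 − prev)(1 − spec)). Under
subtype independence the posterior factorises by component, so each
component is sampled separately in three dimensions and group prevalences
are derived from the paired posterior draws as 1 − ∏(1 − prev_n). The panel
count is a deterministic function of the component results and so adds no
likelihood information of its own.

Sampling uses the emcee ensemble sampler on the logit scale (rare-subtype
posteriors hug zero; the prevalence–specificity ridge traverses better
unbounded), with differential-evolution and snooker moves: 32 walkers, 1000
warmup and 1000 retained steps. Convergence is enforced per component —
split-chain R̂ < 1.05 with walkers as chains and effective sample size
> 400 — and failure raises an error carrying the diagnostics rather than
returning an interval. Chains are reproducible given the seed.

Known behaviour: with uniform prevalence priors, groups composed of many
near-zero components (e.g. a seven-serotype group at ~0.7% true prevalence)
acquire a small upward posterior drift (a few tenths of a percentage
point), because each rare component retains residual posterior mass. Larger
groups, including the full panel, are recovered with intervals covering the
truth.

## Numerical choices

- Probability products are computed as exp(Σ log) when all factors are
  positive, falling back to a direct product when any factor is zero.
- Point estimates are clamped to [0, 1]; unclamped values, denominators and
  clamp counts are always retained in `diagnostics`.
- q_n outside [0, 1] (positivity outside the test's operating range —
  routine sampling noise) is clamped with a log message before products are
  formed.
- Denominators below 1e−12 in magnitude raise an "estimator undefined"
  error instead of returning an enormous estimate; sens + spec ≤ 1 is a
  hard error in every inversion, and a Youden index below 1e−9 triggers a
  conditioning warning.
- Crossover root-finding scans 512 scale factors for a sign change (the
  bias underflows near the feasibility edge, so endpoint signs alone cannot
  distinguish "no crossover"), then bisects to |bias| < 1e−10.
- Distribution scaling solves 1 − ∏(1 − s·w_n) = target by bisection to
  1e−12.
- `ApparentPrevalence` stores counts (floats, so exact expected counts flow
  through the same type); fractions are always derived, never stored.

## Problem sizes used in validation

Coverage studies run 200 replicate cohorts at n = 4000; convergence checks
of the simulator against the forward model use cohorts of 200,000–300,000;
the exact-recovery validation uses 1000 random panels of 1–30 components.
The acceptance script averages the panel estimator over five independent
4000-subject cohorts to damp Monte-Carlo noise in the reported recovery.
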