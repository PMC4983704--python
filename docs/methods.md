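# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical appendix.

## Clinical scales and derived regressors

A visit carries EDSS (0–10, half steps, larger = worse), SNRS (0–100
integer, larger = better), two timed 25-foot-walk (25FW) trials, two
9-hole-peg (9HPT) trials per hand, and the cognitive counts PASAT (0–60)
and SDMT (≥ 0). Any trial may instead end in outright failure. Ten
regressors are derived per visit: EDSS, SNRS, `log2` of the mean of the two
completed trials for each timed test (walk, non-dominant-hand peg,
dominant-hand peg) with a paired 0/1 failure indicator, and PASAT/SDMT
passed through. A failure in either trial dominates: the log term is set to
0 and the indicator to 1. A missing trial (neither time nor failure) makes
the feature missing, never zero.

**Time caps.** Completed walks are capped at 180 s and peg trials at 300 s
(the standard administration limits for these tests); times below 1 s are
clamped to 1 s so log terms are non-negative. The caps also define unit
rescaling: each regressor is divided by its maximum achievable value
(EDSS/10, SNRS/100, log terms by `log2` of the cap, PASAT/60, SDMT by a
configurable maximum of 110), mapping every admissible input into [0, 1].
The published coefficients are consistent with these caps: the failure
coefficients are, to rounding, the log coefficients times `log2` of the cap
(2.409 × log2 180 = 18.05 ≈ 18.056 and 1.305 × log2 300 = 10.74 ≈ 10.751),
so a failed test and a test completed exactly at the cap score within 0.01
points of each other.

**EDSS step set.** The admissible set is {0} ∪ {1.0, 1.5, …, 10.0}; a value
of 0.5 is accepted with a warning since some data sources use a uniform
0.5-step convention.

## The published composite and 0–100 construction

The published score is returned unclamped — the raw linear formula value —
so that it remains a linear function of its inputs for regression and
mixed-model use; clamping to [0, 100] is a presentation choice left to the
caller. Over the admissible region the published scale lies in
[−1, 100.01]: the upper anchor (EDSS 10, SNRS 0, both failures) evaluates
to 100.003, i.e. 100 to the precision of the three-decimal printed
coefficients; the printed intercept 33.166 implies a best-case anchor
slightly below the theoretical best configuration (an untestable choice of
reference times by the original authors), so the formula can dip a fraction
of a point below zero for an unrealistically perfect subject.

`rescale_to_0_100` anchors constructed scales at the *theoretical*
best/worst configurations derived from the scale caps, not at observed data
extremes: this makes the resulting scale cohort-independent and pins its
range to [0, 100] exactly. Given non-negative relative weights `w` on
unit-rescaled regressors with worsening signs `s`, the computing weight on
the raw regressor k is `a·s_k·w_k / max_k` with
`a = 100 / (s_worst − s_best)`, and the intercept is `−a·s_best`.
Relative weights recovered from the published computing weights
(|coefficient| × maximum achievable value, normalized) give EDSS a 27.9%
share of the scale, matching the published description of the composite's
make-up.

## Random-intercept linear-change model

The sensitivity objective is the t-statistic of β1 in
`y_ij = β0 + β1·t_ij + b_i + ε_ij`, `b_i ~ N(0, σ²_b)`,
`ε_ij ~ N(0, σ²_e)`, fitted by REML by default (ML available). The
likelihood is profiled down to the variance ratio λ = σ²_b/σ²_e: for fixed
λ the per-subject covariance `I + λJ` inverts analytically
(Sherman–Morrison), giving closed-form GLS estimates and residual variance,
so estimation is a robust bounded 1-D optimization on log λ (tolerance
1e-8), with the λ = 0 boundary always evaluated explicitly. Denominator
degrees of freedom follow the within-subject-covariate convention
`N_obs − N_subjects − 1`. Exactly noiseless fits (zero residual variance)
return t = ±1e12 with a warning flag instead of dividing by zero, and the
intercept variance is then estimated directly from subject-mean residuals.

For balanced designs (every subject observed at the same times) the GLS
slope equals the within-subject contrast estimate for every λ and the REML
variance components reduce to the classical within/between mean squares, so
a closed-form vectorized path (`balanced_slope_t`) evaluates thousands of
candidate composites per generation during optimization; its agreement with
the general solver (to ~1e-6, including the λ = 0 boundary) and with an
independent grid-search GLS oracle and statsmodels' MixedLM is asserted in
the test suite.

## Weight optimization

Subjects are stratified by baseline test-failure status (combined
walk+non-dominant-peg failure, non-dominant-peg, walk, dominant-peg,
no-failure; the baseline visit is used because it precedes randomization),
and each permutation allocates round(0.7·n) subjects to training by
largest-remainder sampling within strata, so every stratum's training share
differs from 70% by at most one subject.

The genetic algorithm is real-coded over weight magnitudes in [0, 1] per
unit-rescaled regressor; worsening signs are applied outside the search, so
every candidate composite is oriented toward progression. Because a
t-statistic is invariant to positive rescaling of the composite, only the
weight direction matters and candidates are normalized to sum 1 before
fitness evaluation. Operators: tournament selection (size 3), BLX-0.5
blend crossover (probability 0.8), per-gene Gaussian mutation (probability
0.1, σ 0.1, clipped to bounds), 5% elitism; population 50, 100 generations
by default (all configurable). All-zero candidates receive fitness −∞.

The two-stage run mirrors the composite's published derivation: a first
stage over all ten regressors, dropping any regressor whose median
normalized weight falls below 1% of the weight sum (cognitive scales are
sign-pinned at zero when they show learning effects — improvement under
repeat testing — because the sign constraint forbids weights opposite to
progression), then a second stage over the retained regressors whose mean
normalized weights are rescaled to a 0–100 scale and compared against each
single scale on the withheld validation sets (win fractions and mean
t-statistic gains). The whole pipeline is a pure function of
(data, configuration, seed).

## Screening statistics

Relative yearly change is `100·(v(0) − v(−12))/v(−12)`; zero-baseline
subjects are excluded and counted. Outlier fences are `Q1 − 3·IQR` /
`Q3 + 3·IQR` in a single pass, with quartiles by linear interpolation of
order statistics (the numpy default; a Hazen/Tukey-hinge variant is
configurable). If fencing would remove more than a configurable fraction
(default 30%) of subjects — or leaves a zero-variance sample, which happens
for heavily discretized scales whose IQR collapses — the full dataset is
tested instead and flagged. Normality is reported advisorily (skewness and
excess kurtosis against a ±1 rule plus a Shapiro–Wilk test); it never
switches the analysis to a nonparametric test.

Discovery/validation logic: every biomarker is tested (two-sided one-sample
t against zero mean change) in the discovery cohort; biomarkers with raw
p < 0.05 form the carried family, re-tested in each validation cohort with
the step-down Šidák adjustment `adj_(i) = 1 − (1 − p_(i))^(m−i+1)` over
that family (computed via `expm1`/`log1p` for precision, monotonized with a
running maximum). The sensitivity z-score is the cohort mean change divided
by the cohort SD (reported to four decimals); the signal-to-noise ratio is
the mean absolute patient change divided by the mean absolute change in a
caller-supplied stable reference population. Spearman matrices use
pairwise-complete observations (≥ 3 pairs) and a Bonferroni mask at
α/m over the tested pairs.

## Power analysis

Both designs assume linear change: the untreated 2-year mean is twice the
1-year mean with the SD held at the 1-year value, and a drug effect e
shrinks the treated mean by 1 − e, giving the standardized difference
`d = 2·mean·e / sd`. Sample size is the smallest integer n whose exact
noncentral-t power reaches the target (two-sample: df = 2n − 2,
noncentrality d·√(n/2); one-sample: df = n − 1, noncentrality d·√n),
seeded by the normal approximation. The standardized effect size is rounded
to two decimals by default — the precision at which effect sizes are
conventionally entered into trial-design software, and required to
reproduce per-arm figures published from such software; pass
`effect_size_decimals=None` for the unrounded value. From the composite's
observed 1-year change (mean 9.10%, SD 13.23%) this yields 34/53/95
subjects per arm (parallel, 50/40/30% effect) and 19/28/49 (one-group).

## Synthetic cohorts

Each subject follows a latent disability trajectory `d_i(t) = a_i + b_i·t`
on an EDSS-equivalent 0–10 scale. Defaults emulate small progressive-MS
trial cohorts: baseline a_i ~ N(5.5, 1.3²), progression
b_i ~ N(0.03, 0.02²) EDSS-equivalents/month (~0.36 points/year). Links:
EDSS observes the latent value plus N(0, 0.35²) noise, discretized to the
half-point grid (0.5 snapped to 1.0 to honor the conventional step set);
SNRS maps through a decreasing logistic (center 6.5, scale 2) onto 0–100
integers; timed tests are log-normal with medians growing exponentially in
the latent trait (walk: 4·e^0.35d s, peg: 18·e^0.12d s), clipped to
[1 s, cap]; failure hazards are zero below an EDSS-equivalent of 4 and rise
linearly to 0.5 at 7 (peg failures at half the walk hazard), reflecting the
disability range in which ambulation failure emerges; PASAT/SDMT decline
with the latent trait but gain a learning increment (default +1.5 points
per repeat administration) independent of disability. Healthy-volunteer
mode zeroes progression, lowers the baseline and shrinks every noise term.

The feature-level generator used for optimizer-recovery checks shares one
latent trend across d regressors with known loadings and equal iid noise,
so the t-maximizing weight direction is provably proportional to the
loadings. Its default noise (0.02 on the unit scale against a mean latent
drift of 0.048/year) is calibrated so the per-regressor yearly-change
z-scores span ~0.15–0.5 with a composite near 0.8 — the sensitivity
hierarchy observed for real clinical scales in progressive-MS cohorts. At
substantially higher noise the cohort-optimal direction itself departs from
the loadings (verified with a derivative-free oracle), and weight recovery
would measure cohort sampling noise rather than optimizer correctness.

What the generator does *not* emulate: floor/ceiling clustering of real
EDSS distributions, rater effects, correlated measurement noise across
scales beyond the shared latent, visit-time jitter, dropout, and
demographic structure. Passing tests therefore demonstrate correctness of
the machinery under the stated model, not clinical performance of the
composite on new cohorts.

## Problem sizes and numerical conventions

The test suite runs the optimizer-recovery check at 10 seeds × 20
permutations × (population 50 × 100 generations) on 98-subject cohorts,
mixed-model calibration at 500 replicates, screening type-I error at 1000
null biomarkers (n = 35 each), and the power Monte-Carlo at 100,000
simulated trials — sizes chosen to keep Monte-Carlo error well below the
asserted tolerances. Random streams derive from `numpy` `SeedSequence`
spawning, so every pipeline stage is reproducible from a single integer
seed. Ties in stratum allocation break deterministically by stratum name;
the GA's elite set is carried unchanged into each generation.
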