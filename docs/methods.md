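# Methods

## Problem and data model

The package analyses pre/post outcomes of a course of telepractice
speech-language treatment for people with aphasia (PWA). Each patient record
carries demographics (age in years, education in years, a binary African
American indicator, months post stroke onset), an aphasia-type label
(anomic, Broca's, conduction, global), the number of treatment sessions
attended (0–12; the study design offered 5–12), pre/post NOMS
functional-communication levels for verbal expression and auditory
comprehension (integer Likert, 1 = minimal ability to 7 = independence), and
pre/post ASHA-QCL mean scores (1–5).

NOMS levels are ordinal, so the magnitude of change is not comparable across
patients; the outcome analysed is the dichotomy **improved = 1 iff the final
level strictly exceeds the initial level** on the named dimension. Ties count
as no improvement.

## Improvement model

For each NOMS dimension separately:

    improved_i | p_i ~ Bernoulli(p_i),
    logit(p_i) = x_i' beta + u_{g(i)},
    x_i = (1, age_i, months_post_onset_i, education_i, african_american_i),

with varying intercepts u_g for the aphasia-type groups. Covariates enter
unstandardized so each coefficient is a per-unit (per-year, per-month)
log-odds change and exp(beta) is the familiar odds ratio.

Priors (the tunables that matter, with defaults):

| parameter | prior | default scale | why |
| --- | --- | --- | --- |
| fixed effects beta_j | Normal(0, sd²) | sd = 5 log-odds | weakly informative; with n = 20 and quasi-separated subgroups an unregularized fit diverges |
| group intercepts u_g | Normal(0, σ_g²) | — | partial pooling across aphasia types; the singleton global group is shrunk rather than dropped |
| group sd σ_g | half-Normal(0, s²) | s = 2.5 | keeps the 4-group variance estimate proper |

Sampler: Gibbs with Pólya-Gamma augmentation. Each sweep (1) draws
ω_i ~ PG(1, x_i'β + u_g) for every observation, (2) draws (β, u) jointly from
the exact conditional Gaussian with precision W'ΩW + P₀ (W = [X Z]), and
(3) draws σ_g² from its generalized-inverse-Gaussian conditional
GIG(1/2 − G/2, Σu_g², 1/s²), which is what the half-Normal prior on σ_g
implies. Defaults: 4 chains × 2,000 iterations, first 1,000 discarded,
independent spawned RNG streams per chain, fully deterministic given the
seed. A completely one-sided outcome vector raises a separation warning and
the fit proceeds on the strength of the priors.

The unit-shape PG draws use the exact alternating-series rejection sampler
(two-piece truncated inverse-Gaussian / truncated exponential envelope,
threshold t = 0.64), vectorized over observations. Non-integer shapes fall
back to a 200-term truncated convolution of gammas with an analytic mean
correction for the discarded tail (tail variance O(K⁻³)); only the exact
unit-shape path is used in model fitting.

Diagnostics: split-R̂ and mean-method (autocorrelation-summation) effective
sample size, computed by arviz. Chains with exactly zero variance are
reported as R̂ = 1 and ESS = total draw count by convention. Posterior
intervals are equal-tailed quantiles; the summary's odds-ratio column is
exactly exp(estimate).

Oracle: for problems with at most two free coefficients and no grouping,
`grid_posterior_oracle` integrates the exact unnormalized posterior on a
dense uniform grid (±10 prior sds per axis); the test suite requires the
Gibbs posterior mean and sd to agree with it within 0.05 log-odds.

## Cost and value layer

With p the fitted improvement probability and the CPT 92507 per-session rate
(default $108.00, configurable):

* NetCost = rate × sessions attended;
* E(Cost) = p × NetCost. An additive decomposition of the form
  E(p·cost) + E((1−p)·cost) reduces algebraically to the full cost for any
  p and cannot produce a probability-weighted table; the multiplicative
  form is the only one consistent with a per-patient expected-cost column,
  and it is the one implemented.
* value per unit QCL = E(Cost) / ΔQCL, undefined (reported blank, row
  retained) when ΔQCL ≤ 0;
* NetBenefit = ΔNOMS + ΔQCL and
  E(Benefit) = p(ΔNOMS + ΔQCL) + (1−p)(NOMS₀ + QCL₀). These mix Likert
  levels with QCL mean-score units deliberately; no rescaling is invented.

All currency arithmetic is exact (`fractions.Fraction`), so identities such
as value × ΔQCL = E(Cost) hold to equality; rounding — half away from zero,
to cents — happens only at presentation. Cost summaries average over
improving patients only (average = total / improver count, exact before
rounding). Per-type footer ranges of the cost/value table are offered both
pooled across the two NOMS dimensions (min–max) and dimension-separated,
since both renderings are in circulation for singleton groups.

## Synthetic cohorts

The generator's defaults are the study conditions: n = 20; type mix
(0.45, 0.40, 0.10, 0.05); age ~ truncated Normal(60.9, 15.2²) on [18, 100];
education ~ truncated Normal(14.6, 2.3²) on [8, 22]; months post onset
log-normal, moment-matched to mean 40.4 / sd 64.1 (the sd exceeding the mean
is why a symmetric law would be wrong); P(African American) = 0.25; sessions
uniform on {5, …, 12}. Improvement per dimension is Bernoulli with logit
β*·x + u_type, u_type ~ Normal(0, 1) drawn once per cohort; the default β*
are the fitted study coefficients, which reproduce the observed improvement
rates (≈ 45% verbal, ≈ 75% comprehension) at the default covariate mix.

Choices the data do not pin down, made once:

* baseline NOMS levels drawn per type around the observed type means
  (rounded Normal, sd 1), capped at 6 so every patient can improve;
* NOMS gain given improvement: 1 + Poisson(0.5), truncated so the final
  level stays ≤ 7 (no gain-magnitude law is observable from a dichotomized
  outcome);
* QCL change: Normal(+0.9, 0.4²) for patients improving on at least one
  dimension, Normal(+0.1, 0.2²) otherwise, clipped to keep scores in
  [1, 5] — this spans the observed ΔQCL range (0.03–1.4);
* one RNG stream per cohort, explicitly seeded; no global random state.

What the generator does **not** emulate: correlation between the two NOMS
dimensions beyond the shared covariates, session-count dependence of
improvement, measurement error in clinician Likert scoring, attrition.
Passing recovery tests therefore demonstrate that the sampler estimates the
model it states — not that the model is true of any real cohort.

A separate fixture, `synthetic_study_cohort()`, is a hand-constructed
20-patient reconstruction that reproduces the published marginals exactly
where they were published (type/race/improver counts; comprehension
improvers: 15 patients, sessions 5–12, total billed $17,280; verbal: 9
patients, 6–12 sessions, $10,152) with plausible synthetic fill elsewhere.
It is labelled synthetic throughout; it is not patient data.

## Validation design and problem sizes

* PG sampler: empirical means against the closed form (b/2c)·tanh(c/2) at
  10⁵ draws, several tilts.
* Sampler vs oracle: 2-coefficient toy data, 4 × 6,000 iterations, 0.05
  log-odds tolerance on mean and sd.
* Parameter recovery: 50 replicate cohorts of n = 400 at the default β*
  (verbal dimension), 2 × 700 iterations each; every posterior mean within
  3 posterior sds of truth, ≥ 85% empirical coverage of the 95% intervals
  per coefficient, and ≥ 90% sign agreement for every coefficient of
  identifiable magnitude (the 0.002 log-odds/year education slope is
  indistinguishable from zero at this design's information content, so its
  sign is not a recoverable quantity).
* Pipeline: a full default-settings run on a simulated 20-patient cohort is
  verified byte-identical under rerun; every artifact is checksummed in the
  manifest.

The replicate counts and iteration lengths above were chosen as the smallest
sizes at which the checks are statistically meaningful; they are the
package's own validation settings, not estimates of anything clinical.

## Known limitations

* The published regression tables cannot be reproduced number-for-number:
  the raw cohort is unpublished and the original prior and sampler settings
  are unstated. Diagnostics (R̂ ≈ 1, ESS in the low thousands at the default
  4 × 2,000 run) are comparable in magnitude, not equal.
* Some published footer ranges of the cost/value table are not derivable
  from the printed cells under any single min–max rule; the package computes
  self-consistent ranges from its own rows and offers both renderings.
* The significance flagging printed alongside such tables has no stated
  criterion; this package reports credible intervals and leaves flagging to
  the user.
* No model comparison (WAIC/LOO), no probit/cloglog links, no
  magnitude-of-change modelling, no QALY conversion or ICER against a
  comparator arm (the study design has no control group).
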