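# Methods

## The happiness model

Momentary happiness is modelled as a linear readout of exponentially
discounted event histories. For a rating reported after trial *t*,

    Happiness(t) = [w0] + w_reward · S_r(t) + w_perf · S_p(t) + ε,
    S_x(t) = Σ_{j=1..t} γ^(t−j) x_j,         ε ~ N(0, σ),

where the reward regressor is the z-scored chosen-option points and the
performance regressor the z-scored collision-free indicator (1 = clean run).
The discounted sums are evaluated by the recursion `S_t = γ·S_{t−1} + x_t`
(a first-order IIR filter), which is numerically stable and O(n); a test
verifies it against an explicit double-loop evaluation at 1e−12.

Modelling assumptions worth keeping in mind:

* **Linearity and stationarity** — event weights and γ are constant over the
  session; there is no habituation, no interaction between reward and
  performance, and no asymmetry between gains and losses.
* **No expectations** — the model deliberately carries no expected-value or
  prediction-error terms. The task design (well-separated reward
  distributions, staircased performance) is built to estimate the relative
  affective weight of extrinsic vs intrinsic rewards, not expectation
  effects, so expectation-based variants are out of scope.
* **Gaussian observation noise**, independent across probes.

### Conventions

* **z-scoring** uses the population-SD convention (divide by *n*) over the
  subject's full session, free and forced trials alike. A config switch on
  the split-half analysis re-standardizes within block instead.
* **Probe alignment** — a rating reported after trial *t* uses history
  j = 1..t; the rating screen itself contributes nothing.
* **Raw vs standardized ratings** — raw-rating fits (0–100 line, cursor
  midpoint 50) include the baseline w0; standardized-rating fits omit it
  because centred ratings regressed on centred regressors leave no constant
  to estimate. Model comparison always uses standardized ratings so
  subjects with larger rating variance do not dominate.
* The optional pre-task rating is emitted with probe index 0, flagged, and
  excluded from fitting.

## Task simulator

The generator reproduces the study conditions downstream analyses assume:
two options paying Normal(50, 10) and Normal(25, 10) points with the high
option reversing every 19–23 trials (uniform gap); 50% free / 50% forced
choices in shuffled order, forced presentations split equally between the
currently-high and currently-low option; four barriers per trial with a
single any-collision outcome; a happiness probe every 2–3 trials (uniform
gap). Defaults: 120 trials in 2 blocks, giving ≈48 probes per agent —
enough for stable 3–4-parameter fits. All randomness flows from one
generator per agent, seeded from (cohort seed, agent index).

The simulated chooser is a delta-rule value learner with softmax choice.
It exists only to produce plausible choice streams — the affective model is
agnostic to how choices arise. Its defaults (learning rate 0.7, inverse
temperature 0.5 on the points scale) were calibrated once so that cohort
free-choice accuracy lands in the mid-80% range, matching the behavioural
regime the group-level parameters describe; accuracy is a fixture of the
simulation, not a result.

What the generator does **not** emulate: reaction times, per-barrier
kinematics, within-session drift in rating-scale use, non-Gaussian rating
noise, or any dependence of choices on mood. Passing tests therefore show
that the estimation and comparison machinery behaves correctly under the
stated generative process — not that the model is true of human raters.

## PEST staircase

Cursor speed is controlled by Parametric Estimation by Sequential Testing.
Trials accumulate in a run until the Wald deviation
|successes − target·trials| exceeds `wald_w`; then speed steps toward the
target (excess successes ⇒ faster/harder) and the run restarts. Step sizes
halve on a direction reversal, stay on the second same-direction step, and
double from the third onward — except that when a reversal immediately
follows a doubled step the next doubling is postponed by one step.

The classic method leaves its constants to the practitioner; here
`wald_w = 1.0` expected success, initial step 10% of the starting speed,
step clamped to [1%, 50%] of it, and speed clamped to generous physical
bounds. The ~70% fixed point is insensitive to these choices: across
heterogeneous logistic performers the long-run success rate lands at
0.69–0.70 with every run inside [0.65, 0.75]. The small undershoot below
the nominal 0.70 is the expected asymmetry of a staircase holding a
non-midpoint target. Calibration is 60 trials; the in-task continuation is
the same update with the same constants.

## Fitting and model comparison

At fixed γ the weights (and w0) enter linearly, so the RSS objective is
profiled: an ordinary least-squares inner solve per candidate γ, with the
outer search over γ ∈ [0, 1] run by bounded L-BFGS-B from 10 starts
(γ₀ = 0.05 … 0.95; for the separate-γ model a 3×3 grid of starts plus one
at the shared-γ group mean). Ties break deterministically (lowest RSS, then
lowest γ). Convergence tolerance is 1e−8 on the RSS; weights are bounded to
[−10, 10] (standardized mode) and w0 to [0, 100] (raw mode) — bounds that
are never active on sane data since the unconstrained inner solution is
used unless it escapes them. A test confirms the optimizer matches a dense
γ-grid plus closed-form weights to 1e−6 on 20 datasets.

σ is the maximum-likelihood residual SD `sqrt(RSS/n)`, consistent with the
BIC's Gaussian profile likelihood and with σ's exclusion from the parameter
count; it therefore runs slightly low in expectation (≈ `sqrt((n−k)/n)`·σ,
about 4% at n ≈ 48, k = 3). r² is `1 − RSS/TSS` with TSS about the rating
mean; "mean r²" is the across-subject arithmetic mean. BIC is
`n·ln(RSS/n) + k·ln(n)` with k = 2/2/3/4 for the four variants; only
ΔBIC-level conclusions are meaningful since additive constants cancel. The
per-subject significance of individual weights uses a nested
likelihood-ratio χ² test (df = parameter difference, α = 0.05, uncorrected).

## Recovery analyses

Parameter recovery simulates a cohort, fits it with the standard procedure,
and reports Spearman rank correlations between generated and estimated
values; σ recovery doubles as the residual-SD-vs-noise check. Subject-level
parameter estimates from a real cohort are not available to seed the
simulation, so agents draw parameters from normal distributions matched to
the group mean ± SEM with between-agent SD = SEM·√33:

| parameter | mean | SD | truncation |
|---|---|---|---|
| w_reward | 0.39 | 0.23 | — |
| w_performance | 0.18 | 0.17 | — |
| γ | 0.48 | 0.29 | [0, 1] |
| σ | 0.85 | 0.11 | (0, ∞) |

This preserves the population's location and spread — the two quantities
rank-recovery correlations depend on — but not any correlation structure
among a real cohort's parameters, so recovery correlations are comparable
only to within ±0.1 or so. Generated standardized-mode ratings are fit
as-is (no second within-subject z-scoring), keeping recovered weights
unbiased; re-standardizing would shrink or inflate them by the ratio of the
realized rating SD to 1 (≈ 2%).

Model recovery simulates one cohort per generative variant, fits all four
variants to every agent, and tabulates per-agent and summed-BIC winners.
With shared-γ data the separate-γ model fits no better and loses by its
ln(n) penalty; single-term models lose by misfit.

Known estimator behaviour under the default conditions (≈48 probes,
σ = 0.85): recovered weights are unbiased to within Monte-Carlo error;
γ̂ runs ≈0.02 low (boundary truncation at high noise); σ̂ ≈4% low (the MLE
convention above); fitted r² is inflated by roughly k/n ≈ 0.05 relative to
the true signal fraction, which is why cohorts generated at the group-mean
parameters fit at ≈0.28.

## Problem sizes

The test suite and the benchmark script use cohorts of 33 agents × 120
trials (the study-scale configuration), 100–200 agents for bias checks,
10–20 cohort seeds for averaged quantities, and 100 performers × 2,000
trials for the staircase fixed point — sizes chosen so every quantity's
Monte-Carlo error is comfortably below the tolerance being checked while
the whole suite runs in about a minute.

## Limitations

* The chooser and performer are conveniences, not cognitive models; nothing
  about learning or skill should be inferred from them.
* Recovery benchmarks quantify identifiability under the stated generative
  process only; misspecified-noise or drifting-parameter scenarios are not
  covered (the trim/detrend preprocessing exists to probe the latter on
  real data).
* Questionnaire instruments are out of scope; covariate analyses accept any
  numeric per-subject vector.
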