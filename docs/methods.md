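# Methods

## Model

Choices between two-outcome gambles are modelled with cumulative
prospect theory restricted to its four canonical parameters. The value
function is a sign-dependent power function with a single curvature α
shared between the gain and loss domains and a multiplicative loss
aversion coefficient λ; the weighting function is the two-parameter
linear-in-log-odds form, w(p) = δp^γ/(δp^γ + (1−p)^γ), whose curvature γ
produces the inverse-S shape for γ < 1 and whose elevation δ shifts the
whole curve. Gambles confined to one domain are evaluated with
complementary decision weights; mixed gambles weight the gain (carried
with probability p) and the loss (with 1 − p) separately. A logistic
rule maps the utility difference to a choice probability with the
sensitivity k fixed at 1, so no parameter outside the CPT quartet is
estimated; a config override of k exists for sensitivity analysis only.

Because k = 1 acts on raw point-valued utilities (up to ±200), the
logistic saturates on most trials and the likelihood is dominated by
trials near the subjective indifference point. Choice probabilities are
clipped to [1e−12, 1 − 1e−12] before logs so the likelihood stays finite
everywhere in the parameter box; the weighting function is evaluated in
log-odds space, which is algebraically identical to the textbook form
but avoids underflow of p^γ.

On all-loss trials λ multiplies both utilities, so which gamble has the
higher utility never depends on λ — but under the stochastic choice rule
λ still rescales the utility *difference* and therefore the choice
noise. The implementation follows the equations as written; this
subtlety is inherent to pairing a ratio-scale value function with a
fixed-sensitivity logistic and is left visible rather than patched.

## Task generator

The task instrument's published structure is: 126 trials, 42 per type
(gain-only, loss-only, mixed), outcome values in [−200, 200], five
probability levels {.05, .30, .50, .70, .95}, 17 trials with identical
probabilities in both gambles of which 14 are single-domain. The
concrete gamble pairs are not published, so the generator synthesises a
set satisfying every structural constraint, deterministically from a
seed. Choices made where the instrument is silent:

- outcome values lie on a grid of multiples of 5; in single-domain
  trials the less extreme outcome may be 0;
- within a gamble, x is the more extreme outcome (|x| ≥ |y|) and carries
  probability p; in mixed gambles x is the gain and the loss magnitude
  never exceeds the gain magnitude, so both conventions coexist;
- gamble pairs with equal expected value are rejected and redrawn, so
  "optimal choice" is well defined on every trial and the ΔEV analysis
  has no ties;
- trial order is a seeded uniform shuffle;
- the equal-probability census is split 7 gain / 7 loss / 3 mixed, and
  the attainable ΔEV ceiling over the 14 single-domain equal-probability
  trials is recorded in the task metadata.

All counts are configurable (`TaskConfig`); inconsistent requests raise
naming the violated constraint. The distribution of equal-probability
trials over probability levels and their value ranges are generator
choices, not assertions about the original instrument.

## Synthetic cohorts

The default cohort mirrors the study design: HC n=20, GAD n=15, SAD
n=14, OCD n=10. Subject-level parameters are log-normal around group
means (log-scale SD 0.15 by default), which guarantees positivity and
collapses to the group mean at zero dispersion. All groups share
(λ=1.25, γ=0.7, δ=0.9); the OCD α mean (0.55) sits below the HC mean
(0.85) — the one group difference treated as real in the generating
model, mirroring the qualitative clinical finding without asserting
unpublished estimates. Choices are Bernoulli draws from the logistic
rule; timeouts occur independently at a configurable rate (default 0),
carry no choice, cost 5 points, and are excluded from likelihoods.
Clinical severity scores (PHQ-9, GAD-7, BDI, WSAS) are drawn from
normals truncated at zero (clipping) with group means/SDs matching the
published demographics table; a requested parameter–scale correlation is
induced through the subject's standardised log-parameter deviation.

What the generator does **not** emulate: response times, sequential or
learning effects (choices are conditionally independent given
parameters, exactly as the likelihood assumes), within-session fatigue,
and model misspecification of any kind. Passing recovery and calibration
tests therefore shows the estimator is correct *under the model*, not
that real subjects follow CPT.

## Estimation

Per-subject maximum likelihood is the primary path. The negative log
likelihood is minimised over log-parameters inside the box [log 0.05,
log 20] with Powell searches from 8 starts (identity, canonical
published-literature values, two grid corners, a mixed corner, and
seeded jitter), making fits deterministic given data and seed. Records
are aggregated to per-trial choice counts first, which makes the
likelihood invariant to trial order and cheap under task repetition; a
compiled (numba) kernel evaluates it, with an identical pure-numpy path
as fallback and as the reference the tests compare against. Subjects
need a minimum of usable (non-timeout) trials to be fitted (default 50);
others are skipped and listed. Standard errors, when requested, come
from a central-difference Hessian in log-parameters and the delta
method.

Group inference is two-stage: pooled-variance (Student) t tests on the
per-subject estimates, three patient groups versus controls on four
parameters (family of 12, Bonferroni), one-sample t tests of λ against
1, Pearson parameter–clinical correlations (family of 16), and a
two-group mixed ANOVA (via pingouin) on per-trial ΔEV over the 14-trial
equal-probability single-domain subset. Student rather than Welch t is
used so degrees of freedom follow the n₁+n₂−2 convention of the original
analyses; Cohen's d uses the pooled SD (two-sample) or sample SD
(one-sample). Family sizes are explicit arguments everywhere — the
package never hard-codes a corrected threshold.

The hierarchical mode is a deliberately simple approximation to a
nonlinear mixed-effects fit, not a re-implementation of one: it
maximises the joint penalized likelihood in which subject log-parameters
are shrunk toward group fixed effects under Gaussian penalties, with
random-effect SDs profiled parameter-by-parameter on a coarse grid
(default {0.05, 0.1, 0.2, 0.4}; the normalisation term n·log σ keeps the
profile proper) and group contrasts expressed as additive dummy offsets
on the log scale. Wald tests on the offsets use σ̂·√(1/n₁+1/n₂) as the
standard error — a between-subject approximation that ignores
within-subject estimation noise and is labelled as such. Degenerate
variance (identical subjects) floors σ at the smallest grid value with a
warning. Its residual degrees of freedom are its own bookkeeping
(observations minus fixed effects minus subject modes) and are not
claimed to match any particular mixed-model convention.

## Numerical and design choices

- Probability clip ε = 1e−12; likelihood tolerance between kernel and
  reference path is well under 1e−9 on full datasets.
- Powell options: xtol 1e−6, ftol 1e−9, maxiter 2000.
- ANOVA missing cells: listwise deletion with a warning; repeated
  presentations of a trial are collapsed to cell means first.
- Pipeline stage seeds are SHA-256 hashes of (master seed, stage name)
  reduced mod 2³¹, so stages are independently reproducible.
- Equal-probability-trial ΔEV analyses exclude timeouts; a subject with
  no usable subset trials is dropped from that analysis.

## Validation problem sizes

Parameter recovery is checked at 2,016 trials per subject (the task
repeated 16×), requiring every parameter within ±10% of truth. Group
sign recovery uses 20 replicates of a 30-subject two-group cohort on the
full 126-trial task. Null calibration of the 12-test battery uses 200
cohorts of 59 subjects on a reduced 42-trial task with 3 optimizer
restarts — the reduced task keeps per-subject information low but the
test battery's validity does not depend on estimator precision, only on
exchangeability under the null. The hierarchical power check runs at 5
replicates of 10 subjects with a 3-point σ grid.

## Known limitations

- The hierarchical mode's Wald tests are approximate (see above) and its
  σ grid is coarse; it is meant for qualitative agreement with the
  two-stage path, not for exact mixed-model inference.
- With k = 1 and saturated choice probabilities, a subject whose choices
  happen to be perfectly separable can push parameters toward the box
  bounds; the box and the multi-start report (`converged`,
  `n_restarts_used`) make this visible rather than preventing it.
- Clinical-score truncation is by clipping at zero, which slightly
  attenuates requested correlations for scales whose mass lies near 0
  (HC group); the correlation-recovery test uses a patient-like scale
  where the effect is negligible.
- The task generator reproduces published structure, not the unpublished
  stimuli; quantities that depend on the concrete gamble values (e.g.,
  the attainable ΔEV ceiling) are reported per generated task rather
  than assumed.
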