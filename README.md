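# mdmcpt — cumulative prospect theory modelling of risky choice

`mdmcpt` is a Python package for analysing binary gamble choices on the
Michigan Decision-Making (MDM) task with a cumulative prospect theory
(CPT) model. It is aimed at computational-psychiatry researchers who
want to estimate decision-making parameters — value discrimination, loss
aversion, probability weighting — from choice data, compare them across
clinical groups, and validate the whole analysis on synthetic cohorts
with known ground truth.

## The model

Each trial presents two gambles; a gamble `(x, y, p)` pays `x` points
with probability `p` and `y` otherwise (values in [−200, 200],
probabilities in {.05, .30, .50, .70, .95}). Choices are modelled with:

- a sign-dependent power **value function**

  v(x) = x^α  for x ≥ 0,  v(x) = −λ(−x)^α  for x < 0

  where α > 0 is value discrimination (curvature) and λ > 0 loss
  aversion;

- a two-parameter **probability weighting function**, linear in log-odds,

  w(p) = δp^γ / (δp^γ + (1−p)^γ)

  with curvature γ and elevation δ;

- a gamble **utility**: single-domain gambles use complementary weights
  f = w(p)·v(x) + (1−w(p))·v(y), mixed (gain/loss) gambles weight each
  outcome separately, f = w(p)·v(x) + w(1−p)·v(y);

- a **logistic choice rule** P(A over B) = 1 / (1 + exp(k·(f(B) − f(A))))
  with sensitivity k fixed at 1.

Per-subject parameters are estimated by maximum likelihood (multi-start,
gradient-free, over log parameters); group inference runs on the
estimates (two-stage), with a penalized hierarchical mode as an
alternative. A rational benchmark — ΔEV, the expected value of the
chosen minus the non-chosen gamble on equal-probability single-domain
trials — quantifies choice optimality independently of the model.

## Worked example

```python
import mdmcpt as m

task = m.generate_task(seed=0)                      # 126-trial task
cohort = m.simulate_cohort(m.default_groups(), task, seed=42)
fits = m.fit_cohort_two_stage(cohort, m.FitSettings(seed=1))
print(fits.summary())

tests = m.group_parameter_tests(fits.to_frame(), reference="HC", family_size=12)
print(tests[["comparison", "parameter", "t", "dof", "p", "d", "significant"]])
```

Output (abridged):

```
Two-stage cohort fit: 59 subjects fitted, 0 skipped
        alpha     lam   gamma   delta
group
GAD    0.9619  1.4814  0.7215  0.8062
HC     1.0026  1.3467  0.7306  0.8514
OCD    0.5376  1.4074  1.1464  1.0270
SAD    1.0270  1.4945  0.7561  0.8550

comparison parameter      t  dof     p      d  significant
 HC-vs-OCD     alpha  5.105   28 0.000  1.977         True
 HC-vs-GAD     alpha  0.464   33 0.646  0.158        False
 ...
```

The synthetic cohort places the OCD group's generating value
discrimination (α = 0.55) below the control mean (0.85) and leaves every
other parameter equal across groups. The two-stage pipeline recovers
exactly that structure: of the 12 Bonferroni-corrected comparisons, only
the HC-vs-OCD α test is significant (t(28) = 5.11; degrees of freedom
follow the pooled-variance convention n₁+n₂−2 = 28). A one-sample test
of the controls' fitted loss aversion against 1 gives
`mean = 1.347, t(19) = 4.015, p = 0.0007` — losses loom larger than
gains for the simulated controls, as their generating λ = 1.25 implies.

The same workflow is available from the shell:

```bash
mdm run --seed 0 --out runs/demo          # full pipeline + manifest
mdm generate-task --seed 0 --out task.csv
mdm validate-task task.csv
```

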