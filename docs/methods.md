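# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## The composite ordinal score

Each patient-day is scored

```
score = min(daily_cap, episode_weight · episodes) + med_unit_weight · med_units
```

with defaults `episode_weight = 1`, `med_unit_weight = 1`,
`daily_cap = 6` score units. One "antianginal unit" is half a
guideline maximum daily dose of one agent, so a patient on one agent
at full dose contributes 2 units. The published scale's exact level
table is not public in full; these defaults reproduce its structural
properties — strictly monotone in both inputs, zero iff the day is
symptom- and medication-free, episode contribution capped — and every
weight is a `ScoreConfig` field, so the true table can be dropped in
without code change. Three clinical override categories sit strictly
above every numeric value, ordered unblinding for intolerable angina
< acute coronary syndrome < death; within a patient the worst category
wins.

Missing daily values are filled by last-observation-carried-forward at
the daily-score level; override days are never overwritten. Days
missing before the first observation take the first observed value so
the filled sequence is total (only a fully missing sequence is
rejected); with ~0.3% missingness this branch is almost never taken.

The per-patient follow-up summary is the worst override category if
any occurred, otherwise the mean daily score over the final
`summary_window_days = 7` days of follow-up. A trailing-week mean was
chosen over the single last day (noisy under a daily count outcome)
and over the whole-phase mean (which would dilute a constant late
treatment effect); the window is configurable. The pre-randomization
summary is the mean over the whole run-in phase.

## Ordinal analysis of covariance

The primary model is the proportional-odds cumulative link model with
logistic link: P(Y ≤ c_k | x) = expit(α_k − xβ). Distinct numeric
summary values each form a category ("continuous-ordinal" treatment,
which the likelihood permits); `max_numeric_levels` optionally
quantile-bins them for very small samples. Override categories are
appended above the numeric levels. For expected-score summaries each
numeric category represents its own value and the overrides take
values 1, 2, 3 units above the numeric maximum — an explicit, and
replaceable, scoring of clinically dominant states.

Fitting: thresholds are reparameterized as α_k = α₁ + Σ_{j≤k} exp(δ_j)
so any real parameter vector yields a valid ordering, and the exact
negative log-likelihood is minimized by L-BFGS with analytic gradients
(target gradient norm 1e-8; starting values are the empirical
cumulative logits with β = 0). The covariance matrix is the inverse
observed information, obtained by central differences of the analytic
gradient in the original (α, β) coordinates at the maximum. Complete
separation is reported through `fit.converged`/`fit.message` rather
than raised, so simulation loops can skip such replicates explicitly.
With two outcome categories the model reduces exactly to binary
logistic regression, which the tests verify against statsmodels; the
statsmodels `OrderedModel` serves as an independent cross-check of the
full likelihood, never as the implementation.

Baseline adjustment uses a restricted cubic (natural) spline with 4
knots at quantiles (.05, .35, .65, .95) — Harrell's convention — built
from the truncated-power construction, linear beyond the boundary
knots; the fit falls back to a linear term when the covariate has too
few distinct values. Orientation: the treatment indicator marks the
placebo arm, so an odds ratio above 1 means higher (worse) scores
under placebo. Confidence intervals are Wald at 95% throughout, with
no multiplicity adjustment.

## Secondary endpoints

Continuous endpoints use OLS ANCOVA on complete cases; freedom from
angina (questionnaire angina-frequency score of 100) uses logistic
regression; CCS class (ordinal 0–IV) reuses the cumulative link model
with a linear baseline term (five levels leave little room for a
spline). "Typical patient" predictions are made at the mean baseline
for exercise/imaging endpoints and the median for questionnaire and
ordinal endpoints. The multiple-imputation sensitivity analysis draws
m = 20 imputations from a Bayesian normal linear model of follow-up on
treatment and baseline (σ² from its scaled inverse-χ² posterior, β
from the conditional normal, residual noise added), refits the ANCOVA
on each completed set, and pools by Rubin's rules with Barnard–Rubin
adjusted degrees of freedom — chosen so that with no missing data the
pooled interval reduces to the complete-case t-interval.

## Blinding index

For one true-arm stratum the index is (n_correct − n_incorrect)/n,
i.e. (2·P(correct | guessed) − 1)·P(guessed): 0 under random guessing,
1 under complete unblinding, negative for opposite guessing. The CI is
a Wald interval from the multinomial variance of the ±1/0 contrast,
truncated to [−1, 1], with no continuity correction (strata of n ≈ 150
do not need one). Certainty sub-levels (sure/unsure) are tabulated but
collapse to direction for the index; 3-category tables are accepted by
leaving the `*_sure` counts at zero.

## Power calculation

The design computation for the two-sided two-sample t-test uses the
normal-theory power formula (per-arm n = 2(z_{1−α/2} + z_{power})²σ²/δ²
and its inversion), under which a 2-unit difference at σ = 6 and
α = 0.05 needs 284 patients for 80% power — the self-consistent
convention for this design. The exact noncentral-t power of the
realized t-test is available via `method="exact"`; it is lower by
about 0.3 points at this size (0.799 at n = 284, exact sample size
286), a discrepancy the package reports rather than hides. A
Monte-Carlo power estimator validates both.

## The synthetic generator

Daily angina counts are Poisson conditional on a patient-level gamma
frailty with mean 1 and variance `frailty_dispersion = 1` — a
negative-binomial marginal, since daily symptom counts are
overdispersed across patients. The placebo daily rate is 0.7
episodes/day and PCI multiplies the post-randomization rate by
`pci_rate_ratio = 0.43`, reproducing observed arm means of ~0.3 vs
0.7 episodes/day. Medication follows a deterministic contact rule:
one unit step (to a maximum of 4) whenever the trailing 7-day episode
mean exceeds `contact_threshold = 2.5`, never stepping down within a
phase, and resetting to zero on the day of randomization (run-in
medication is stopped). Each unit attenuates the episode rate by the
factor 0.85. The threshold was set so simulated follow-up medication
use (~0.04/0.25 units/day by arm) matches the low observed daily
antianginal use; the true contact protocol is a dose-sequence table
this rule stands in for. Randomization is 1:1 in shuffled blocks of
size 8–16; patients simulated asymptomatic through the run-in are
redrawn, mirroring withdrawal of asymptomatic patients. Override
events are mutually exclusive per patient with probabilities
(1/300, 10/300, 0) for (unblinding, ACS, death) — the observed event
frequencies, with no deaths — at a uniform random follow-up day;
death truncates the diary. Diary days are missing completely at
random at 0.3%. Secondary endpoints are drawn at the endpoint level
(Gaussian with arm effects, ordinal CCS from arm-specific
probabilities, a shared severity driver linking them weakly to the
frailty); they emulate marginal behaviour, not mechanism. Blinding
guesses are multinomial with 20% correct / 60% don't know per arm.

What the generator does **not** emulate: informative missingness,
medication non-adherence, within-patient episode autocorrelation
beyond the frailty, nitroglycerin use (excluded from the score),
enrollment flow, and the mechanistic link between ischemia and
exercise endpoints. Passing tests therefore demonstrate correctness
of the analysis machinery under the stated generative assumptions,
not robustness to violations real data may show.

## Problem sizes used in validation

The estimator-recovery study simulates 1000 proportional-odds trials
of 100 patients per arm with a true treatment odds ratio of 2.21 and
checks that the mean log-odds-ratio is within 3 Monte-Carlo standard
errors of the truth and that 95% CI coverage is nominal. The
null-calibration study runs the full simulate → score → analyze
pipeline on 500 trials of 100 patients per arm at rate ratio 1 with
no overrides and checks CI coverage of OR = 1. A fixed n = 12,
three-category dataset pins the optimizer against a brute-force
grid-plus-simplex maximization of the same likelihood to 1e-4. These
sizes give tight Monte-Carlo error while keeping the whole suite
inexpensive to run.

## Known limitations

* The exact published level table of the composite score and the true
  medication protocol are supplementary material not reproduced here;
  both are configurable stand-ins.
* Wald intervals are used everywhere (profile-likelihood or bootstrap
  intervals are not implemented); with ~100 categories and n ≈ 300
  they are accurate but not exact.
* The longitudinal (daily-level) modeling of the score is out of
  scope; the analysis summarizes follow-up per patient first.
* `typical_patient_prediction` warns rather than refuses on
  extrapolation beyond the observed baseline range.
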