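# anginatrial

Tools for designing, simulating and analyzing placebo-controlled trials
of angina therapy whose primary endpoint is a **composite daily ordinal
angina symptom score**.

In such a trial, patients stop antianginal medication, record angina
episodes daily on a smartphone diary through a symptomatic run-in, are
randomized 1:1 to intervention (PCI) or a placebo procedure under deep
sedation, and are followed blind for 12 weeks while medication is
restarted only through patient-initiated contact. Each patient-day is
scored from the number of angina episodes and the units of antianginal
medication in use — zero means no angina on no medication — and three
clinical events override the scale from above: unblinding for
intolerable angina < acute coronary syndrome < death. This package is
for trialists and statisticians who want that design's full analysis
pipeline as reusable, tested code driven by a synthetic trial
generator, since individual patient data from such trials are not
public.

## The model

The primary analysis is an **ordinal analysis of covariance** using a
proportional-odds cumulative link model. For ordered outcome
categories *c*₁ < … < *c*_K (distinct follow-up score values, with the
override categories on top),

P(Y ≤ *c*ₖ | x) = logit⁻¹(αₖ − xβ),  α₁ < … < α_{K−1},

where x contains the treatment indicator (1 = placebo, so the
treatment odds ratio e^β > 1 means *worse* scores under placebo) and a
restricted cubic spline in the pre-randomization score. Because the
likelihood uses only the outcome's ordering, no distributional
assumption is placed on the score. The model is fit by quasi-Newton
maximization of the exact likelihood with analytic gradients and an
increasing-threshold reparameterization; Wald intervals come from the
observed information. Model-derived "typical patient" follow-up values
per arm are Σₖ *c*ₖ·P(*c*ₖ | arm, median baseline).

Around the primary analysis the package provides: OLS ANCOVA and
logistic/ordinal models for secondary endpoints, Rubin-pooled
multiple-imputation sensitivity analyses, the arm-specific blinding
index (correct − incorrect)/n with Wald CI, and the two-sample t-test
power calculation used to size such trials.

## Worked example

```python
from anginatrial import (TrialConfig, generate_trial, score_trial,
                         fit_cumulative_link, odds_ratio)

trial = generate_trial(TrialConfig(n_per_arm=150, seed=42))
scores = score_trial(trial.diary).merge(trial.patients, on="patient_id")
fit = fit_cumulative_link(
    outcome=list(scores.followup_score),
    treatment=(scores.arm == "placebo").astype(float),
    baseline=scores.pre_score.to_numpy(),
)
print(odds_ratio(fit))
```

Running `python examples/03_primary_analysis.py` (the same computation
with the typical-patient summary) prints:

```
patients analyzed   : 300
outcome categories  : 32
odds ratio (placebo worse): 5.38 (95% CI 3.46 to 8.36)
Wald p-value        : 8.09e-14
typical-patient follow-up score, PCI    : 0.31
typical-patient follow-up score, placebo: 0.73
```

The simulated intervention cuts the daily angina rate to 43% of
placebo's, so placebo patients sit higher on the ordinal score scale:
the odds of a placebo patient exceeding any given score level are ~5
times those of a PCI patient, and the model-derived follow-up score
for a median-baseline patient is about twice as high under placebo.
The other scripts in `examples/` demonstrate the power calculation,
the generator, the full endpoint report, and the blinding index.

A thin CLI wraps the same functions:

```bash
anginatrial simulate --n-per-arm 150 --seed 42 --out trial/
anginatrial analyze --data trial/ --out report.json
anginatrial power --target-power 0.8 --delta 2 --sd 6
```

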