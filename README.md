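# updatebias

Hierarchical Bayesian modelling of **positive update bias**: how strongly
people integrate positive (vs. merely neutral) social feedback into their
self-beliefs about a public performance — their *self-evaluation* of a speech
they just gave, and their *self-efficacy* for an upcoming one.

The package is written for computational-psychiatry and social-neuroscience
researchers who run speech/feedback paradigms of this kind: participants rate
their performance on 40 attributes (0–10 visual analog scale), receive a fixed,
experimenter-controlled set of judge scores (20 neutral in 4–6, 20 positive in
7–10), and re-rate themselves afterwards. Because such datasets are rarely
public, the package ships a synthetic-cohort generator with the exact
statistical structure the model assumes and known ground-truth bias, so every
stage of the analysis is testable end to end.

## The model

For subject *s* and item *q*, the five scores — pre-speech self-efficacy
(y₁), post-speech self-evaluation (y₂), judges' feedback (y₃), post-feedback
self-evaluation (y₄), post-feedback self-efficacy (y₅) — are jointly
multivariate normal with subject means μ_s (the y₃ mean is known and fixed per
condition) and a condition-specific covariance,

```
y_{s,q} ~ N(mu_s, Sigma_pos_s)   if item q received positive feedback
y_{s,q} ~ N(mu_s, Sigma_neu_s)   otherwise,
Sigma_s = diag(tau_s) @ Omega_s @ diag(tau_s)
```

so the 5×5 correlation matrices Ω carry the quantities of interest. The
per-subject **update-bias indices** are the correlation contrasts

```
self-evaluation update bias = Omega_pos(y3, y4) − Omega_neu(y3, y4)
self-efficacy  update bias  = Omega_pos(y3, y5) − Omega_neu(y3, y5)
```

A second model variant labels items by the sign of the prediction error
y₃ − y₂ instead of the absolute feedback score; the two are compared by
10-fold cross-validated expected log pointwise predictive density (ELPD) with
the 2-standard-error preference rule. Group-level bias is assessed from the
posterior of the across-subject median (95% highest-density interval);
individual differences are profiled by a varimax-rotated PCA of a 12-scale
questionnaire battery and related to the bias indices, with the between-
condition prediction-error imbalance regressed out.

Posterior inference uses a blocked Gibbs sampler with conjugate full
conditionals (Gaussian means, inverse-Wishart subject covariances with a
learned Wishart group-level scale giving partial pooling); see
`docs/methods.md` for priors, diagnostics and design choices.

## Worked example

```python
import numpy as np
from updatebias.cohort import CohortConfig, simulate_cohort
from updatebias.model import MCMCSettings, ModelSpec, extract_bias, fit_model
from updatebias.inference import group_bias_hdi

cohort = simulate_cohort(CohortConfig(n_subjects=50, n_items=40), seed=7)
draws = fit_model(cohort.ratings, ModelSpec(), MCMCSettings.profile("ci", seed=1))
bias = extract_bias(draws)

est = bias.point_estimates.merge(cohort.truth, on="subject_id",
                                 suffixes=("_est", "_true"))
r = np.corrcoef(est.self_efficacy_bias_est, est.self_efficacy_bias_true)[0, 1]
print(f"recovery r(posterior mean, truth) = {r:.2f}")
hdi = group_bias_hdi(bias, "self_efficacy")
print(f"group median self-efficacy bias = {hdi.point:.3f}, "
      f"95% HDI [{hdi.hdi_low:.3f}, {hdi.hdi_high:.3f}] -> {hdi.decision}")
```

prints

```
recovery r(posterior mean, truth) = 0.73
group median self-efficacy bias = 0.098, 95% HDI [0.024, 0.182] -> positive_bias
```

The recovery correlation says the posterior-mean bias indices track the
generating per-subject truth (drawn uniformly over [−0.3, 0.5]) about as well
as 20 items per condition allow. The group result reflects this cohort's true
mean bias of +0.1: the 95% HDI of the across-subject median excludes zero, so
a group-level positive bias is established. A cohort generated with zero true
bias instead yields an HDI straddling zero (`not_established`).

A command-line interface mirrors the library
(`updatebias simulate|assign-feedback|fit|compare|validate|run`); e.g.

```bash
updatebias run --seed 1 --out run_dir      # simulate -> fit -> compare -> report
```

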