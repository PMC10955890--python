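# Methods

## The rating model

Each (subject, item) observation is the 5-vector of speech scores
(y₁ pre-speech self-efficacy, y₂ post-speech self-evaluation, y₃ judges'
feedback, y₄ post-feedback self-evaluation, y₅ post-feedback self-efficacy) on
the 0–10 visual-analog scale. The model treats the vector as multivariate
normal with subject-level means and one of two subject-level covariances,
selected by the item's feedback condition. Decomposing each covariance into
scales and a correlation matrix, Σ = diag(τ)·Ω·diag(τ), puts the scientific
quantity — how strongly feedback covaries with the post-feedback ratings —
into two cells of Ω per condition, and the per-subject update-bias indices are
the positive-minus-neutral contrasts of those cells. Values are modelled
unstandardized on the rating scale; normality is a deliberate simplification
(ratings are bounded and discrete; a censored or Beta-CDF likelihood would be
faithful but far more expensive), so extreme means plus clipping can mildly
attenuate correlations near the scale ends.

The mean of y₃ is not estimated: the feedback schedule is experimenter-
controlled, so the per-condition y₃ means are fixed constants. For the
valence-split model they are the means implied by the printed score inventory
(101/20 = 5.05 neutral, 165/20 = 8.25 positive); for the prediction-error
split, whose conditions are not experimenter-controlled, they are computed
once from the pooled data at fit time.

Two labellings are supported: *valence split* (positive iff y₃ ≥ 7, the
scale's designed positive range) and *prediction-error split* (sign of
y₃ − y₂). In the PE split, items with exactly zero prediction error are
modelled with the element-wise average of the two conditions' τ and Ω. The
averaged-covariance reading is an interpretation: the source description of
this rule ("priors ... defined based on the average of the parameters
estimated for the positive and negative PE questions") is ambiguous between
the prior and the likelihood; averaging in the likelihood keeps the model
generative and needs no two-stage fit. Because PE signs are strongly
unbalanced in this design, a subject may have almost no negative-PE items; the
PE model therefore tolerates empty condition cells (they are informed by
pooling alone), whereas the valence model requires ≥ 2 items per condition.

## Priors and sampling

No probabilistic-programming backend is used; the model's full conditionals
are conjugate, so inference is a blocked Gibbs sampler written directly in
NumPy and vectorized across subjects:

- **Subject means** (4 free components; the y₃ mean is fixed):
  μ_s ~ N(g, diag(v)) with Gaussian full conditional combining both
  conditions' precision.
- **Subject covariances**: Σ_{s,c} ~ Inverse-Wishart(ν, S_c), ν = 10. The
  conditional is again inverse-Wishart; ν sets the strength of pooling toward
  the group scale matrix (prior weight ≈ ν pseudo-items against the ~20 real
  items per condition). When zero-PE items are present their likelihood
  couples Σ_pos and Σ_neu, so the conjugate draw becomes a
  Metropolis–Hastings proposal accepted with the zero-PE likelihood ratio
  (acceptance is high: at most 4 of 40 items are affected).
- **Group level**: g ~ N(5, 2.5²) per component and v ~ Inverse-Gamma(2, 2)
  (prior mean variance 2, i.e. a between-subject SD of ~1.4 rating points);
  S_c ~ Wishart(7, Φ₀) with Φ₀ chosen so the implied prior covariance is
  diag(1.5²) — 1.5 rating points is a typical within-subject spread across 40
  attributes. Both conditionals are conjugate (Gaussian/inverse-gamma;
  Wishart for S_c), so subject covariances are partially pooled toward a
  learned group covariance per condition.

Two MCMC profiles are provided: `ci` (4 chains × 500 warmup + 500 kept) and
`paper` (4 chains × 1500 warmup + 10,000 iterations thinned by 4, i.e. 10,000
retained draws). The Gibbs chains mix fast (split-R̂ ≈ 1.005 and bulk ESS >
1000 at the `ci` profile on study-sized cohorts); `check_convergence` reports
split-R̂ and bulk ESS for the subject means, scales, the two bias cells per
subject and the group means, with the pass rule R̂ < 1.1 and ESS > 1000.
There are no divergent transitions in a Gibbs scheme; the corresponding
failure mode here is a rejected Cholesky, guarded by symmetrizing the scatter
matrices and a 1e-8 ridge (relevant only for degenerate, near-constant
ratings). Per-draw pointwise log-likelihoods are stored for every observation,
which makes ELPD computation exact rather than re-derived.

## Feedback-schedule generator

The task's score inventory is fixed: {4×6, 5×7, 6×7, 7×5, 8×7, 9×6, 10×2},
i.e. 20 neutral (4–6) and 20 positive (7–10) scores. Items are assigned scores
so the prediction error (score minus the integer-rounded expectation) stays in
the believable band [−2, +4] whenever the remaining inventory allows, with at
most 4 exact hits (PE = 0). The algorithm first forces items whose expectation
admits an in-band error in only one condition (rounded expectation ≤ 2 →
neutral; ≥ 9 → positive), splits the rest uniformly at random, then fills
scores greedily in random order, sampling uniformly among in-band scores and
falling back to the smallest excess beyond the band (ties broken toward the
positive side) only when none remains. Randomized restarts keep the attempt
with the fewest, then smallest, out-of-band errors; an instance whose every
assignment violates the null-PE cap (e.g. all expectations equal to a
7-count score) raises with the binding constraint named. Trial order is drawn
by rejection sampling, which is exactly uniform over orderings with no run of
more than two same-condition trials.

## Synthetic cohort

The generator emulates the study conditions: 50 subjects × 40 items; subject
means drawn around (5.3, 5.0, 5.6, 5.9) for (y₁, y₂, y₄, y₅) with
between-subject SD 1.3 (the observed rating means and spreads); within-subject
scales 1.5; the y₃ scale matched to the within-condition spread of the fixed
inventory (0.805 neutral / 0.942 positive), which makes the within-condition
sample correlation a consistent estimate of the generating Ω cell. Judges'
scores are *conditioned on*, not sampled: each subject gets a schedule from
the task generator and the remaining four scores are drawn from the
4-dimensional conditional normal given y₃ (Schur complement), mirroring the
experimenter-controlled design and keeping recovery well-posed.

Correlation templates put moderate coupling (0.4–0.5) among the self-ratings
and weak coupling of y₃ with the pre-feedback scores. The feedback-coupling
cells Ω(y₃,y₄) and Ω(y₃,y₅) sit at a midpoint of 0.55, split ± bias/2 between
the conditions, with per-subject bias drawn uniformly (default range
[−0.3, 0.5]). The midpoint matters: with 20 items per condition the sampling
SD of a correlation is ≈ (1−r²)/√20, so the attainable correlation between
estimated and true bias is information-bounded; couplings near 0.55 reflect
how strongly post-feedback ratings track well-recalled feedback and make the
documented recovery level (r ≥ 0.7 at the study scale) attainable, whereas
weak couplings (~0.4) cap it near 0.65 for any estimator. Subject-level
heterogeneity comes from Fisher-z jitter (SD 0.05) on all correlations with
projection back to the nearest valid correlation matrix (eigenvalue floor
1e-6) and lognormal jitter (SD 0.10) on the scales; the recorded ground truth
is always the realized Ω difference after projection, exactly.

The questionnaire battery (12 scales) is generated from two latent factors —
"social sensitivity" and "self-negativity" — plus unique noise, with
self-esteem loading negatively on self-negativity and the reward-sensitivity
scale left mostly unique (emulating a battery whose minor third component is
driven by a single questionnaire). The self-negativity factor is given a
configurable correlation with the true self-efficacy bias (default −0.29).
This generator is a stand-in for testing the profiling stage only: real
questionnaire data have skewed, discrete scales and richer cross-loadings, so
passing tests show the PCA/correlation machinery is correct, not that real
batteries have two factors.

With `discretize=True` ratings are rounded to the 0.1 VAS grid and clipped to
[0, 10] (the realistic data product; Kolmogorov–Smirnov distance to the
continuous marginals stays ≤ 0.1 at mid-scale means); the continuous default
matches the model's assumptions and is used for model-focused tests.

## Downstream inference

- **Group bias**: on each posterior iteration the median of the per-subject
  bias is taken across subjects; the decision uses the shortest 95% interval
  of that distribution (computed by the shortest-sorted-window method) and
  declares a positive bias only when the interval lies above zero.
- **Model comparison**: within-subject item folds, stratified by condition
  (10 folds by default ⇒ 2 items per condition per fold); the held-out unit is
  the 5-score vector of one (subject, item). Held-out log predictive density
  is the log posterior-draw-averaged likelihood; SE(Δ) uses the paired
  pointwise differences. Folds cross items rather than subjects because
  subject-level parameters cannot be predicted for unseen subjects without
  further assumptions.
- **Prediction-error control**: ordinary least squares of each per-subject
  quantity on ΔPE (mean PE on positive minus neutral trials), residuals
  re-centered at the original mean. Both the component scores and the bias
  indices are residualized before correlating (the analysis language supports
  either; a flag selects).
- **PCA profiling**: eigen-decomposition of the scale correlation matrix,
  retention by eigenvalue > 1, varimax rotation (via statsmodels), components
  oriented so the bulk of loadings is positive, regression-method scores.
  Component–bias correlations report raw two-tailed p values alongside
  Benjamini–Hochberg-adjusted ones; decisions default to raw, matching the
  original reporting convention.
- **Mediation**: whole-case resampling percentile bootstrap (5000 draws) of
  the indirect effect a·b from three OLS fits; the identity c = c′ + a·b holds
  to numerical precision. This utility takes any three aligned series; in this
  package it is exercised on synthetic stand-ins.

## Validation statistics

Friedman's ANOVA (tie-corrected, via pingouin) with Kendall's W = χ²/(n(k−1));
one-sample Wilcoxon signed-rank with the tie-corrected normal approximation
and effect size r = |Z|/√N (N the full sample size — this reproduces the
worked example r = 0.77 from Z = 5.41, N = 50); paired t with Cohen's d in the
average-of-condition-SDs form, which reproduces d = 3.40 from the condition
summaries 4.23 ± 0.37 vs 2.92 ± 0.40 (the difference-SD form does not);
one-way repeated-measures ANOVA (pingouin) with partial η² and FDR-controlled
post hoc paired tests, without sphericity correction. All p values are
two-tailed. Fully degenerate inputs (identical repeated columns) return null
statistics rather than NaN.

## Problem sizes

The test suite and acceptance script run everything at the design scale where
that is cheap (50 subjects × 40 items for recovery, group inference and
posterior predictive checks; 1000 random schedules for the generator suite)
and at reduced scale where many refits are needed: model-selection
self-consistency uses 10 cohorts of 20 subjects × 20 items with 5 folds and
shortened chains, and the null-calibration check uses 5 zero-bias cohorts.
These sizes are the package's own verification design; the conclusions they
support are qualitative (which model wins, whether the HDI covers zero), and
at these sizes the effects measured are far from the decision boundaries.

## Known limitations

- The normal likelihood ignores the bounded, discrete rating scale; biases
  from clipping grow for subjects whose means sit near the scale ends.
- Inverse-Wishart priors couple scales and correlations; with 20 items per
  condition the data dominate, but very small per-condition item counts lean
  on the pooled group scale.
- The PE-split model's zero-PE handling (averaged covariance in the
  likelihood) is one reading of an ambiguous rule.
- Bias point estimates are posterior means (chosen for linearity); medians
  would differ slightly for skewed posteriors.
- The questionnaire generator's two-factor structure is deliberately simple;
  it validates machinery, not psychometric realism.
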