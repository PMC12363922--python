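# Methods

`resprec` models the choice of first respiratory support — high-flow nasal
cannula (HFNC) versus noninvasive ventilation (NIV) — for ICU patients
flagged as high-risk for invasive mechanical ventilation (IMV) by an
early-warning score. It combines a counterfactual individualized-
treatment-effect (ITE) engine with a deterministic clinical-guideline rule
engine, and provides the concordance and chart-review analyses used to
evaluate such a hybrid system. Everything is exercised end-to-end on a
synthetic cohort with known causal ground truth.

## Synthetic cohort

Each encounter carries a latent severity scalar `s ~ N(0,1)` that drives
vitals and labs (eight channels sampled on an irregular grid over the 48 h
before the high-risk timepoint T0), the early-warning risk score (a noisy
monotone transform of the measured severity component), treatment
assignment, and both potential outcomes. Treatment follows a logistic
propensity whose covariate/severity coupling is scaled by
`confounding_strength`; setting it to 0 recovers randomized assignment
exactly. Both potential IMV outcomes are Bernoulli draws from logistic
models sharing a base risk (severity, SOFA, age) plus arm effects
`effect_niv` / `effect_hfnc` and a zero-mean effect modifier built from
COPD status and a hypoxemia score, scaled by `het_strength`. The true ITE
`P(IMV|NIV) − P(IMV|HFNC)` is therefore available in closed form per
encounter. A mortality model sharing severity plus a small hospice
process supports the composite mortality/hospice endpoint.

Default conditions: n = 2000 encounters, confounding_strength = 1,
effect_niv = +0.3, effect_hfnc = −0.3 (log-odds), het_strength = 0.8,
missing_rate = 0.3. These produce IMV rates near 26%, roughly balanced
arms, and a true-ITE standard deviation of about 0.12 — magnitudes in line
with the ICU populations this tool targets.

Guideline facts (COPD exacerbation, de novo hypoxemic failure, NIV
intolerance, ...) are Bernoulli draws whose probabilities are shifted by
covariates through a mean-preserving perturbation
`p_i = p + c·p(1−p)·(f_i − E f)`: the requested marginal prevalence is
preserved exactly while facts remain correlated with comorbidities and
hypoxemia. Blood gases are drawn so that hypercapnia-prone encounters meet
the respiratory-acidosis criterion (pH ≤ 7.35, PaCO2 > 45 mmHg) with a
configurable probability. Pseudo-notes are deterministic templated
sentences, exactly invertible by the bundled extractor.

What the simulator does **not** emulate: real physiological waveforms and
cross-channel dynamics, informative missingness, multi-site heterogeneity,
nonlinear outcome surfaces, or documentation noise in notes. Passing the
recovery suites therefore demonstrates the estimator's behaviour under a
transparent logistic data-generating process, not clinical performance.

## Feature pipeline

Measurements are resampled into hourly bins (half-open intervals aligned
backward from T0; bin value = mean of the bin's measurements), with a
24-bin grid by default. Missing bins are forward-filled while the most
recent observation is at most 24 h old, otherwise imputed with the frozen
training-cohort channel mean; the mask is exposed as extra binary
channels. Three derived values per channel: baseline (first observed value
of the encounter), local trend (least-squares slope over a trailing 6 h
window; 0 with fewer than two points), and time since last measurement at
T0. Statics (demographics, comorbidity flags, SOFA, Charlson index, the
risk score) are appended; the column order is recorded in a manifest.
Grid length and trend window are configurable; the defaults are this
package's own choices.

## Counterfactual engine

**Stage 0 — balanced counterfactual regression.** Each arm's IMV risk is a
sparse linear logistic score on the standardized features, and the
representation Φ(x) is the 2-vector of arm scores. The two scores are fit
jointly to convergence by accelerated proximal gradient descent (FISTA)
under

* a lasso penalty at level `0.3·sqrt(log d / n_arm)` per arm (the usual
  high-dimensional scaling; d ≈ 420 features at n ≈ 1000 per arm), and
* a fused-lasso tie between the two coefficient vectors at 0.3 of that
  level. The fusion shares statistical strength on the common risk
  surface and shrinks spurious between-arm differences; without it, two
  independent fits hallucinate effect heterogeneity from estimation noise
  whenever the true effect is null.

A second phase adds the integral-probability-metric balance term: an
entropic-regularized 1-Wasserstein cost between the arm-wise
representation distributions (Sinkhorn on 256-per-arm subsamples, plan
held fixed in the gradient). The final state is the one with the best
held-out factual log-loss along the balancing trajectory, the unbalanced
solution included — balancing may help the counterfactual fit but is
never allowed to degrade the factual one. With `alpha = 0` and
`fuse_ratio = 0` the estimator reduces exactly to two independent per-arm
regressions, which is also the "naive plug-in" baseline used in the
recovery comparisons.

A convex score-based instantiation was chosen over a deep encoder
deliberately: at the package's default problem size (n = 2000, ~420
features of which most are noisy hourly bins) deep two-head encoders
either memorize before learning the differential signal or over-shrink it,
while the converged sparse fit ranks true effects reliably. The
representation is low-dimensional but sufficient for the downstream
stages, and every step is deterministic given the seed.

**Standalone 1-Wasserstein estimator.** Exact in 1-D via the pooled-CDF
integral (equal-size sets reduce to the sorted-matching formula); exact
optimal assignment for equal-size multivariate sets; Sinkhorn otherwise.

**Stage 1 — conditional outcome flow.** The binary outcome is uniformly
dequantized onto [0, 2) and its conditional density given (Φ(x), arm) is
modelled by a conditional normalizing flow: a stack of four
context-conditioned affine layers interleaved with sinh–arcsinh
transforms. Every layer is smooth, strictly monotone, has a closed-form
inverse and a tractable log-Jacobian; scale and skew parameters are
bounded through tanh so the map cannot degenerate. Conditioners are small
tanh networks (32 hidden units) trained by Adam with cosine-annealed step
size on the exact maximum-likelihood objective (gradients by the package's
own reverse-mode tape). Class probability is recovered by thresholding
samples at 1.

**Stage 2 — interventional adjustment.** A second conditional flow maps
the treatment-conditioned Stage-1 latent to the shared N(0,1) base. At
prediction time the interventional latent is drawn from its
treatment-*marginal* law: base draws are pushed through the Stage-2
inverse under arm assignments drawn from the cohort's marginal treatment
frequency. Conditioning the latent on the counterfactual arm instead
would reproduce the selection encoded in the factual latents and
manufacture treatment effects on null cohorts; the marginal draw removes
that pathway while Stage 1 retains the legitimate (representation, arm)
conditioning. Common random numbers — the same base and marginal-arm
draws for both counterfactual arms — couple the two samples and shrink
the Monte-Carlo variance of the ITE.

**Decision rule.** ITE = P(IMV|NIV) − P(IMV|HFNC); recommendations are
NIV-preferred below −0.001, HFNC-preferred above +0.001, Indifferent on
the closed band between (boundaries inclusive). The threshold is a
parameter; wide bands (e.g. 0.05) are used to check that null-effect
cohorts come out Indifferent-heavy.

**Attribution.** Feature rationales are sampling-based Shapley values of
the ITE surface against a mean-feature background (permutation chains,
batched evaluation). Attributions sum exactly to ITE(x) − ITE(background)
per sampled permutation; the top-50 ranked list feeds the recommendation
prompt.

## Guideline engine

The NIV side encodes the strong indications (COPD exacerbation with
respiratory acidosis; cardiogenic pulmonary edema; neuromuscular disease
or obesity-hypoventilation with acidosis; prophylactic post-extubation use
in high-risk patients) and the conditional ones (immunocompromised with
mild-to-moderate failure, post-operative failure, chest trauma). The HFNC
side evaluates its exclusion first — established hypercapnic acidosis
without NIV contraindication/intolerance rules out first-line HFNC — then
the indications (de novo hypoxemic failure; post-operative post-extubation
high-risk; NIV intolerance with moderate/severe failure; moderate/severe
failure without an NIV indication). Absent measurements propagate as
*unknown* through tri-state logic and never fire a criterion.

Conventions this package defines (the source rubric leaves them open):
confidence is "high" for an unambiguous strong indication or a clean No,
"medium" when only conditional indications fire, "low" when the verdict
rests on unresolved unknowns; a stated NIV contraindication forces No
regardless of indications; the joint label is NIV for Yes/No, HFNC for
No/Yes, and Indifferent for ties or any Either. Model/guideline alignment
is true when the labels agree or the guideline verdict is Indifferent.

An adapter protocol lets an external large language model replace the rule
evaluator; the default adapter *is* the rule engine, so the pipeline is
fully offline and deterministic. Adapter settings (model name, temperature
0.1) are recorded metadata. The response parser validates the structured
schema leniently, accepting the corrupted key spellings that appear in the
published schema table (`NIVjecommendation`, `ModeLalignment`, ...).

## Concordance analysis

Encounters are concordant when the recommended and received first
therapies match, discordant when crossed, and excluded from rate strata
when the recommendation is Indifferent. Rates are percentages from
unrounded counts (2 decimals); the comparison columns are
`100·(total − concordant)/total` (relative reduction if concordant) and
`100·(discordant − total)/total` (relative increase if discordant) — these
reproduce the published table cells from the published rates, except one
cell (10.00) that the source evidently computed from unrounded
intermediates (we obtain 10.01 from the printed rates; see the rate-table
tolerance notes in the tests). The adjusted analysis is a maximum-
likelihood logistic regression (IRLS via statsmodels) of the outcome on
both concordance indicators plus age, gender, Charlson index, SOFA and
the risk score; Indifferent encounters stay in the regression with both
indicators 0.

## Chart review

The review rubric captures guideline congruence, explanation accuracy
(incorrect content, clinical significance, missing content), harm
likelihood/extent, three physician agreement votes, and comprehension/
retrieval/reasoning flags. An *accuracy error* is any of incorrect
content, missing content, or a retrieval error/hallucination; harm fields
must be "na" exactly when no accuracy error is flagged, and harm
percentages use the error-subset denominator. Overall physician agreement
is the majority of the three votes with "partially agree" counted as
disagreement — a convention this package defines, chosen because it
reproduces the published 13/20 overall tally from per-reviewer votes.
Percentages round half-up to integers (7/11 → 64%).

## Problem sizes and numerical choices

The recovery suites run at n = 2000 encounters (three seeds) for PEHE and
rank-correlation, n = 5000 for the planted odds-ratio recovery, and a
2000-train/500-test split for the null-effect check — sizes at which the
generating signal is comfortably identifiable while the full suite stays
lightweight. FISTA runs 1500 iterations (well past convergence at these
sizes); the balancing phase 300 proximal steps; flows train 150 epochs
with batch 256. Sinkhorn uses a relative regularization of 0.05 with 150
iterations; its matching quality against the exact 1-D oracle is itself a
test. Degenerate inputs raise typed errors: single-arm cohorts, constant
outcomes (separation), non-finite losses, empty sample sets.

## Known limitations

The Stage-0 representation is linear in features; strongly non-additive
effect modification would require the configurable penalties to be relaxed
and a richer encoder. Stage 2's marginal-latent reading is one of several
defensible formalizations of the second-stage adjustment; it is validated
here by "does not degrade, and recovers nulls", not identified from the
source's equations. The guideline engine operates on structured facts —
free-text understanding is out of scope, and templated pseudo-notes are a
round-trip fixture, not clinical NLP. Review summaries implement one
aggregation convention; alternative conventions (e.g., partial = half
agreement) are easy to add but would change the overall-agreement
percentage.
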