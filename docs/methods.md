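# Methods

This note documents the models, algorithms and design choices behind
`mosr`, in the spirit of a statistical software appendix: what is
computed, under which assumptions, and what the synthetic validation
does and does not establish.

## 1. The prediction problem

The target is a binary indicator of death within one year of major
elective non-cardiac surgery, predicted from pre-operative variables:
39 clinical parameters (demographics, comorbidities, medications,
laboratory values, surgical specialty) and 46 cardiopulmonary exercise
testing (CPET) summaries (oxygen uptake at peak and anaerobic
threshold, ventilatory equivalents, end-tidal gases, oxygen pulse,
heart rate, workload, …). At ~5.5% prevalence the outcome is rare
enough that accuracy and AUC are weakly informative; the analysis
centres on F1, sensitivity and specificity.

## 2. Synthetic cohort generator

Real perioperative cohorts of this kind are single-institution and not
redistributable, so the package generates cohorts that emulate the
study conditions.

**Marginals.** Continuous features are truncated normals parameterised
by (median, spread, hard range); where a published median/IQR/range
summary exists it is used directly, with spread = IQR/1.349 (the
normal-theory conversion). A truncated normal cannot match an
arbitrary median/IQR/range triple exactly, so the IQR match is
approximate by design. Binary comorbidities and medications are
Bernoulli with the published proportions; sex, ethnicity and surgical
specialty are categorical with the published frequencies. Features
without published summaries (most laboratory values and secondary CPET
variables) use plausible adult perioperative values chosen once and
fixed; they exist to give the feature selector a realistic search
width, not to carry signal.

**Dependence.** All features flow through a Gaussian copula. Declared
pairs receive rank correlation (default: peak V̇O₂ with anaerobic
threshold, ρ = 0.7 — a physiological plausibility choice); everything
else is independent. This understates the dependence web of real CPET
panels; see §8.

**Outcome mechanism.** Death is Bernoulli with logit
η(x) = β₀ + Σⱼ fⱼ(xⱼ), where each planted effect fⱼ is either linear
(coefficient × centred value) or a threshold indicator. The defaults
realise the qualitative risk directions the analysis is meant to
recover:

| feature | transform | coefficient |
|---|---|---|
| peak VE·V̇CO₂⁻¹ | linear, centred at 34.5 | +0.15 per unit |
| BMI | 1[BMI > 28 kg·m⁻²] | −0.8 |
| peak VE·V̇O₂⁻¹ | 1[value > 38] | −0.6 |
| previous myocardial ischaemia | linear (binary) | +0.7 |

The ventilatory-efficiency term is deliberately dominant
(logit SD ≈ 0.8 versus ≤ 0.4 for the others). The intercept β₀ is not
hand-set: it is calibrated by Monte Carlo (100 000 draws of the effect
features from their marginals, fixed internal seed) and a root find so
that E[expit(β₀ + η)] equals the 5.5% target. Calibration is a
property of the configuration, not of the simulation seed; over 20
seeds at n = 5000 the mean observed prevalence sits within ±0.5
percentage points of target (checked in the acceptance suite).

**Missingness** is MCAR, cell-wise at a configurable rate, never
touching the outcome. The real missing-data mechanism of the study
population is uncharacterised; MCAR is the neutral choice and exists
mainly to exercise complete-case filtering.

**Determinism.** Every stochastic stage draws from a named substream
of one master seed (`mosr._rng`), so identical (config, seed) pairs
reproduce byte-identical cohorts and pipelines.

## 3. Preprocessing

Complete-case filtering drops any row with a missing cell (a missing
outcome is a schema violation, not missingness). Binary features are
coded 1 = present. Nominal features are one-hot encoded with **no
reference level dropped**: the symbolic-regression engine selects
features itself, so indicator collinearity is harmless, and full
indicator sets keep formulas readable. Continuous features are min-max
scaled to [0, 1]; parameters are fitted on the training set only and
applied without clipping to test data (out-of-range test values keep
their ordering). A constant fitted column maps to 0, keeping the
feature inert. Ordinal clinical scores (ASA physical status) are
treated as continuous.

The 80/20 split is stratified with an exact allocation rule: each
outcome class contributes ⌊0.8 × class size⌋ training rows and the
seats remaining to reach round(0.8 n) go to the largest class first.
On 1190 patients with 66 events this yields 952/238 patients and 52/14
events deterministically — the floor of 66 × 0.8 = 52.8 gives 52, and
the negative class absorbs the remainder seat.

## 4. The engine

**Representation.** Formulas are rooted trees over the operator set
{add, sub, mul, div, neg, log, exp, sqrt, min, max, if_greater} plus
feature leaves and real constants (uniform in [−2, 2], matched to the
0–1 scaled features). All operators are protected so that finite
inputs always give finite outputs: div(a, b) = 1 when |b| ≤ 1e−12,
log uses max(|x|, 1e−12), the exp argument is clamped to ±50, sqrt
takes |x|, and every node output is clamped to ±1e100 (which closes the
remaining overflow route through repeated multiplication). `if_greater`
(a 4-ary conditional) lets threshold effects be expressed directly.

**Objectives.** For a tree with raw scores s, probabilities are
p̂ = expit(s) clipped to [1e−12, 1 − 1e−12]; the objective vector is
(BCE, 1 − F1) at the 0.5 threshold, both minimised. Single-class
label vectors are rejected (F1 is meaningless for selection there).

**Search.** Ramped half-and-half initialisation (depths 2–6, maximum
depth 17), binary tournaments on (non-domination rank, crowding
distance), subtree crossover with probability 0.8, subtree or point
mutation with probability 0.2, and elitist μ+λ survival via fast
non-dominated sorting with crowding-distance truncation. Boundary
members of the splitting front carry infinite crowding distance and
always survive, which makes the per-generation best of each objective
monotone non-worsening — an exact invariant the tests assert on the
run history. The final front is the rank-0 set deduplicated by
serialized formula.

**Model selection.** The front member with the lexicographically best
(AUC, sensitivity, specificity) on supplied evaluation data wins; full
ties go to the smaller tree, then to formula order. AUC-first keeps
selection threshold-free. A consequence worth knowing: at ~5.5%
prevalence the AUC-best member is often roughly calibrated, its
probabilities rarely cross 0.5, and its F1 at that threshold can be 0
even when discrimination is real. The classification threshold is a
config knob for exactly this reason. The evaluation protocols select
on an inner 90/10 validation split so front members that overfit
training noise lose.

**Defaults.** Population 300, 500 generations — the study-scale
budget. Tests and the acceptance script use smaller budgets, stated
below.

## 5. Evaluation protocol

The metric panel (accuracy, sensitivity, specificity, F1, PPV, NPV) is
computed from the confusion table at threshold 0.5; any 0/0 ratio is
reported as an explicit undefined marker rather than a silent 0, with
one standard exception — F1 is 0 when TP = 0 while FP + FN > 0. AUC is
the Mann-Whitney statistic (ties count ½). Calibration uses ten
equal-width bins on [0, 1], the last bin right-closed, empty bins kept.

Hyperparameter search is a grid over {population size, mutation
probability, maximum depth} scored by 10-fold stratified
cross-validation; inside each fold the training portion is divided
90/10 (stratified), the 10% part feeding the trainer's model
selection. The mean F1 on the fold hold-outs picks the winner, ties
going to grid order. Test performance is summarised over 10 runs on
random stratified 90% subsets of the test set (fresh substream per
run), reporting mean and SD per metric with undefined values excluded
and counted.

## 6. Shapley attribution

Attributions use the interventional (marginal) value function: v(S) is
the mean model output with coalition features fixed to the explained
patient's values and the rest drawn from a background sample (default
100 training rows). Enumeration over all 2^k coalitions is exact and
additivity holds to machine precision for k ≤ 12; wider models use a
permutation sampler (one background row and one feature order per
permutation) that is unbiased for the exact value, reports a
per-feature Monte Carlo SE, and restores exact additivity by spreading
the final residual proportionally to |attribution|. Features a formula
provably never references get attribution 0 without computation (the
null-player axiom). Attributions are computed on the probability scale
by default — the scale on which classifier beeswarm plots are read —
with the raw-score scale behind a flag. Feature importance is mean
|attribution| across patients; each feature's direction is the
correlation between its attribution and its value.

## 7. Validation design and problem sizes

The published quantities that are pure protocol arithmetic (952/238
split with 52/14 events; 5.5% and 1.9% mortality from 66/1190 and
23/1190) are recomputed exactly. Everything else is validated against
planted structure, at desk-scale budgets chosen so the whole suite
runs in minutes on one CPU:

* **Oracle equivalences** (exact): tree evaluation vs an independent
  per-row recursive evaluator (1000 cases); non-dominated sorting vs an
  O(n²) dominance oracle (populations to 200); AUC vs exhaustive
  pairwise concordance (sets to 50); the metric panel vs scikit-learn
  (500 random tables).
* **Planted-signal recovery**: features x ~ N(0, 2²) with logit
  coefficients +3/−3, n = 2000, prevalence 0.5. The feature spread was
  fixed by a design-stage power analysis: with unit-variance features
  the Bayes-optimal F1 is ≈ 0.88, so no learner could clear a 0.9 bar;
  at SD 2 the Bayes limit is ≈ 0.94, leaving the bar testing the
  learner rather than the noise floor. Budget: population 100, 50
  generations; the selected model clears test F1 ≥ 0.9 in ≥ 4 of 5
  seeds.
* **Direction recovery**: default-condition cohorts at n = 6000
  (population 250, 80 generations, validation-based selection,
  Shapley over 50 patients against a 100-row background). The larger
  cohort is the package's choice: at n = 1190 the training set holds
  only ~50 events and the search reliably latches onto noise features
  regardless of budget (measured up to the full 300 × 500 setting).
  At n = 6000 the dominant planted feature ranks first in the SHAP
  summary with a positive direction in 5/5 test seeds.

## 8. Known limitations

* **Secondary-effect recovery is unreliable at desk scale.** The
  protective BMI > 28 sign is recovered in only a minority of runs at
  any budget tried (including the full study-scale budget): a
  threshold effect worth ~0.37 logit SD at 5.5% prevalence changes
  training BCE by ~0.004, which the evolutionary search finds only
  sporadically once the dominant term is in place. The corresponding
  acceptance check asserts the strict criterion and currently fails
  its BMI clause; the per-seed evidence is printed in the failure
  message. Interpret it as a statement about search budget, not about
  the attribution machinery (which is validated exactly in §6 terms).
* The generator emulates declared marginals, one declared correlation
  pair and a four-term additive outcome; real cohorts have dense
  correlation structure, nonlinear physiology and informative
  missingness. Passing synthetic tests shows the pipeline recovers
  structure it is told to plant — not that the same budgets suffice on
  real data.
* Min-max scaling is fitted on training data only; whether the original
  protocol scaled before or after splitting is unknowable from the
  publication, so a flag allows whole-dataset fitting for comparison.
* F1 at the fixed 0.5 threshold is near-degenerate for calibrated
  models at 5.5% prevalence (§4); threshold choice is exposed but no
  threshold optimisation is performed.
* Exact Shapley enumeration is capped at 12 features; beyond that the
  sampler's SE, not machine precision, bounds accuracy.
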