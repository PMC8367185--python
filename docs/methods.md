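# Methods

## Problem and model

`t2dreco` learns sequential treatment policies for type 2 diabetes from
visit-level EMR-style data and evaluates them retrospectively.  Three models
are supported, one per treatment type: antiglycemic, antihypertensive and
lipid-lowering.  Each recommendation combines a *knowledge-driven* candidate
filter (declarative clinical rules) with a *data-driven* ranking from an
offline deep Q-network: the rules select admissible actions, the Q-network
ranks them by expected cumulative clinical reward.

### State

A visit is encoded as a 49-dimensional vector: 9 continuous variables (age,
diabetes duration, HbA1c, SBP, DBP, LDL-c, TG, BMI, eGFR; min-max scaled to
[0, 1] with 0.5th/99.5th-percentile bounds fitted on training data and
clipped), 2 binary demographics, a 4-level ethnicity one-hot with an
explicit "Other" level, 8 medical-history flags, 9 rule-derived disease-risk
flags (renal-function thresholds at 60/45/30, macro-/microvascular history,
above-target indicators for glycemia, blood pressure and LDL-c, HbA1c>9),
and 17 previous-drug indicators (one per drug class across the three
treatment types).  The exact composition lives in one module
(`featurize.py`) so alternative schemes are pluggable; the fitted scheme
serializes to YAML so train-time and recommend-time encodings are
bit-identical.

### Actions

* Antiglycemic (13, *delta* semantics): no change; dose increase/decrease of
  the three most commonly titrated drugs (metformin, basal insulin, premixed
  insulin); adding one of 7 oral antidiabetic classes; switching to one of 3
  insulin regimens.  An action is inferred from a consecutive prescription
  pair with the precedence insulin-regimen switch > OAD addition > dose
  change > no change; multiple added OADs resolve to the lowest canonical
  index and mixed dose directions to the largest relative change.  The text
  the action tables come from also states a 14-dimension network output;
  since only 13 actions are enumerated, the package uses 13 and surfaces the
  discrepancy here.
* Antihypertensive (16) and lipid-lowering (8, *subset* semantics): the
  action is the index of the currently prescribed drug-class subset in the
  canonical row order (A/B/C/D classes; statin/fibrate/ezetimibe).

### Rewards

Per transition, from next-visit outcomes, with coefficients a=1, b=2, c=4
and targets HbA1c<7 %, SBP/DBP<140/90 mmHg, LDL-c<2.6 mmol/L:

* glycemic: `a·sgn(7 − HbA1c') − b·Hypo − c·Final·CX`
* blood pressure: `a·(+1 if SBP'<140 and DBP'<90 else −1) − c·Final·CX`
* lipid: `a·sgn(2.6 − LDL') − c·Final·CX`

`sgn(x)` is +1 for x>0 and −1 otherwise, so a value exactly at target counts
as uncontrolled (consistent with the strict "<" goals).  `Hypo` is a severe
hypoglycemia admission in the inter-visit interval; `CX ∈ {−1, +1}` encodes
any complication or death over the 6-year horizon and enters only at the
final visit (`Final`).  The attainable glycemic range is exactly [−7, +5].
The blood-pressure reward's joint-control form mirrors the glycemic/lipid
structure; it is isolated in one function for easy revision.

### Q-network and training

Fully connected 49 → 64 → 32 with batch normalization and leaky-ReLU after
each hidden layer; the last hidden layer splits into a state-value stream
and an advantage stream recombined as Q = V + A − mean(A) (dueling).
Training is offline: the replay buffer is the fixed set of retrospective
transitions; there is no environment interaction and no exploration.  Each
iteration draws a prioritized batch (priority |TD error| + 10⁻³, exponent
α=0.6, importance exponent β=0.4, weights normalized by their maximum),
forms double-DQN targets (evaluation network selects the argmax action, the
Polyak-tracking target network values it; τ=0.01 per iteration), minimizes
the importance-weighted squared TD error plus a magnitude penalty
λ·max(|Q| − r_reg, 0) with λ=0.5 and r_reg=4, and takes one Adam step
(η=0.001, batch 256, gradient clipped at global norm 10).  γ=0.9.

Everything is plain NumPy with hand-written gradients (verified against
finite differences in the tests), which makes training bit-deterministic
for a given seed.

Two additions beyond the printed recipe proved necessary for stability in
the offline setting, where rarely-logged actions receive no direct Bellman
grounding and their extrapolated Q-values otherwise grow without bound:

1. **Target clipping**: bootstrapped targets are clipped to ±14, a bound on
   plausible discounted returns given rewards in [−7, +5] and 3–6-monthly
   visit sequences.
2. **Conservative value penalty** (weight 0.5): the soft-maximum of Q over
   all actions at sampled states is penalized and the logged action's Q is
   raised by the same weight, the standard conservative Q-learning device
   that prevents unsupported actions from winning the argmax through
   extrapolation alone.

Both are isolated `TrainConfig` fields and can be switched off; the toy-MDP
recovery tests run with them off so the unregularized Bellman fixed point is
recovered exactly.  Training length is configurable up to the 100,000
iteration maximum; the bundled demonstrations and tests use 2,500–10,000
iterations, sized to the ~15,000-transition synthetic cohorts they train on.

### Knowledge rules

Rules are declarative (YAML): predicate conditions over visit fields and
derived `on_<drug-class>` flags, plus forbidden/forced action indices.  The
shipped set contains the two renal-dosing rules (no metformin dose increase
below eGFR 45; discontinue metformin below eGFR 30, which removes every
metformin-retaining action; never start metformin below eGFR 30) and a
treat-to-target rule (at HbA1c ≥ 7 % the no-change and de-intensification
actions are not candidates).  The full guideline corpus is deliberately not
reconstructed; the format exists so sites can add rules.  If rules forbid
everything, the recommender falls back to "no change"/"no drugs" with a
warning — conservative inaction is the safest visible default.  Q-ties break
toward the lower canonical index, which favors less aggressive actions.

## Cohort construction

Malformed numeric cells and non-positive values of positive-valued labs are
treated as missing at load.  Missing labs/measurements are imputed by last
observation carried forward within 1 year, then by the population median;
per-row provenance is recorded.  Trajectories pair consecutive visits 3–6
months apart (months = 30.4375 days); the patient's first recorded visit is
assumed to start from an empty prescription.  Visits after death are always
dropped; visits lacking the treatment's prescription record, or whose labs
were entirely missing pre-imputation, are dropped; in long-term mode visits
after the first occurrence of the outcome's complication are dropped.  The
final surviving pair is terminal: its reward carries the complication term
evaluated over the 6-year horizon, and it is not bootstrapped.  Splits are
at the patient level (8:2 by default), deterministic given a seed.

## Synthetic registry

The simulator's purpose is statistical structure, not clinical fidelity:
its job is to exercise every pipeline assumption (sequential visits,
treatment-responsive dynamics, confounding by indication, outcome hazards
tied to control) while keeping the exactly optimal policy computable.

* **Dynamics**: each biomarker follows AR(1) relaxation toward a
  drug-dependent set-point, e.g. HbA1c' = (1−κ)·HbA1c + κ·sp(drugs) + ε with
  κ=0.7 (treatment response largely complete within one 3–6-month interval),
  ε ~ N(0, 0.4), untreated set-point 9.5 % and a physiologic floor of 5.5 %.
  Each OAD class subtracts a configured pull (0.8–1.6 %), insulin regimens
  subtract 2.6–4.0 %, dose titration ±0.25 % per step.  SBP/DBP and LDL-c
  follow the same form with per-class pulls.
* **Hypoglycemia**: severe-admission probability is logistic in insulin
  intensity (0/1/2) and depth of control, so intensive insulin at tight
  control is penalized — the mechanism that makes "maximal treatment
  always" suboptimal.
* **Complications/death**: per-interval event probabilities from annual
  base hazards (0.8–1.5 %/year) scaled by exp of biomarker excess above
  target; one first event per type per patient; death stops follow-up;
  events after the last visit are simulated over the 6-year horizon.
* **Behavior policy**: severity-dependent preference weights (clinical
  inertia below target, escalation above), a 15 % uniform-random coherent
  action rate representing practice variation (and giving the offline
  learner coverage of rare state-action cells), and confounding by
  indication because aggressive choices concentrate in sicker patients.
* **Follow-up**: 8–16 visits per patient, gaps mostly 3–6 months with 10 %
  outside the window, matching a multi-year registry panel.

What it does not emulate: measurement error structure of real labs, drug
contraindication patterns beyond the shipped rules, adherence dynamics,
secular drift, inter-drug interactions.  Passing tests therefore show the
pipeline's statistical machinery is correct under its stated assumptions,
not that the learned policies are clinically valid.

### Oracle

Value iteration on the simulator's own MDP: states are HbA1c bins (40 bins
over 4–16 %) crossed with reachable drug configurations (OAD subset ×
insulin regimen × titration level, enumerated breadth-first from
untreated); transitions use the AR(1) law discretized by the normal CDF;
rewards come from the reward module with the expected hypoglycemia penalty;
convergence tolerance 10⁻⁶.  The oracle policy is the benchmark for policy
recovery and the upper reference in end-to-end tests.  Offline Q-learning
from 2,000 simulated patients recovers roughly the oracle's strategy
(escalate above target, prefer high-efficacy additions, intensive insulin
for marked hyperglycemia) and lands far above the behavior policy, with a
residual mean per-transition reward gap to the oracle of about 0.2-0.25
depending on the cohort seed — the expected cost of learning from a
confounded fixed dataset without interaction.  The end-to-end test asserts
the gap at the 0.2 level, so its outcome at that boundary is seed-dependent.

## Evaluation framework

* **Short-term**: visits are split by model concordance (physician's
  inferred action equals the model's top-1 at drug-class level; uninferable
  actions are excluded, not counted as nonconcordant).  Goal-achievement
  3–6 months later is compared by χ² test and crude OR (Haldane-corrected
  on zero cells); confounders are adjusted by main-effects logistic
  propensity scores with inverse-probability weights truncated at the
  1st/99th percentiles, then a weighted logistic regression with robust
  (HC0 sandwich) standard errors — model-based SEs are invalid under
  weighting.  Stratified analyses repeat the pipeline within current-HbA1c
  bands (<7, [7, 9), ≥9; the 7–9 band is closed on the left).
* **Long-term**: per-patient concordance rate = concordant visits / total
  visits.  Binned occurrence curves (bin width 0.2) with OLS slopes over
  non-empty bins; multivariate logistic regression of each outcome on the
  three per-treatment concordance rates with a baseline risk score
  covariate.  Risk scores are out-of-fold probabilities from a gradient
  boosted classifier (XGBoost; penalized logistic fallback), so a patient's
  own outcome never trains their score.  The horizon is fixed at 6 years;
  earlier-censored patients contribute observed follow-up (logistic, not
  survival, modelling — matching the evaluation design this reproduces).
* **Adherence-heterogeneity experiment**: to verify that the long-term curve
  analysis detects a planted protective effect, cohorts are simulated where
  each patient's physician follows the model's recommendation with a
  per-patient probability drawn independently of severity; concordance then
  carries a purely causal protective effect and the fitted slopes are
  negative in essentially all cohorts.  Under the purely observational
  behavior policy the slope is confounded (sicker patients are both more
  escalated and more event-prone) and its sign is not stable — itself a
  useful illustration of why the IPW adjustment exists.

## Numerical and design choices

* Dates at day resolution; months = 30.4375 days, years = 365.25 days.
* Exactly-at-target values count as uncontrolled everywhere ("<" goals).
* Duplicate (patient, date) rows and double deaths are load-time errors;
  malformed numerics are not.
* Empty admissible action sets fall back to index 0 with a warning.
* The propensity model is main-effects logistic; truncation percentiles are
  configurable.
* Batch normalization uses batch statistics during optimization and frozen
  running statistics (momentum 0.99) at evaluation; evaluation determinism
  is part of the contract.
* Checkpoints are JSON (parameters, running statistics, config, feature-
  scheme fingerprint) — text, diffable, loadable without pickle.

## Known limitations

* Unified therapeutic targets; no personalized goals.
* The dose-titration actions cover only the three named drugs.
* Offline Q-learning inherits the behavior policy's support: actions never
  logged in a state region cannot be ranked reliably there, which is why the
  conservative penalty and the knowledge filter matter.
* The evaluation measures association, not causal effect; IPW removes only
  measured confounding.
* The simulator's oracle covers the antiglycemic model; the subset-action
  treatments reuse the same machinery but their optimal policies are not
  separately benchmarked.
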