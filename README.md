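# t2dreco

Offline reinforcement-learning treatment recommendation for type 2 diabetes
mellitus, with the retrospective evaluation framework needed to judge such a
recommender from observational data, and a synthetic EMR registry simulator
to exercise the whole pipeline end to end.

**Who it is for.** Researchers in clinical machine learning and
pharmaco-epidemiology who want a complete, testable reference implementation
of the "knowledge + data" recommendation design: a guideline rule filter
selecting admissible medications, and an offline dueling double-DQN ranking
them by expected long-run clinical benefit — plus the concordance-based
outcome analyses (χ², propensity-score inverse-probability weighting,
weighted logistic odds ratios, long-term concordance-rate curves and
regressions) used to evaluate it retrospectively.

## The model

Patient trajectories are sequences of outpatient visits 3–6 months apart.
A visit is a 49-dimensional state s (demographics, history, disease-risk
flags, drugs in use, labs and physical measurements).  The action a is the
prescription change at that visit — one of 13 antiglycemic delta actions, or
one of 16 / 8 drug-class subsets for antihypertensive / lipid-lowering
therapy.  The reward scores the next visit, e.g. for glycemic therapy

    r_t = a·sgn(7 − HbA1c_{t+1}) − b·Hypo_{t+1} − c·Final_{t+1}·CX_{t+1},

with a=1, b=2, c=4: +1 for reaching the HbA1c<7 % target, −2 for a severe
hypoglycemia admission, and ∓4 at the final visit according to whether any
complication or death occurs over a 6-year horizon.  A dueling double-DQN
(49 → 64 → 32, batch norm + leaky ReLU, Q = V + A − mean A) is trained
offline on the fixed transition set with prioritized experience replay,
soft target updates (τ=0.01), discount γ=0.9, and a regularizer that
penalizes Q-values beyond the maximum attainable reward.  At
recommendation time, the knowledge rules (renal metformin dosing,
treat-to-target intensification) restrict the action set and the Q-network
ranks the survivors; a visit is *model-concordant* when the physician's
actual prescription change equals the top-ranked action at drug-class
level.

Because real diabetes registries cannot be redistributed, the package ships
a simulator that reproduces the statistical structure such data has —
treatment-responsive AR(1) biomarker dynamics, confounding by indication,
outcome hazards tied to biomarker control — with a value-iteration oracle
for ground truth.  See `docs/methods.md` for every modelling choice.

## Worked example

`examples/04_concordance_evaluation.py` simulates a 600-patient registry,
trains the antiglycemic model, and runs the short- and long-term
evaluations:

```
concordance rate:              34.0% of visits
HbA1c<7% incidence, concordant:    86.6%
HbA1c<7% incidence, nonconcordant: 55.2%
crude OR:                      5.25
IPW-adjusted OR:               1.46 (95% CI 0.90-2.39)
long-term occurrence slope:    -0.308 per unit rate
mean policy reward  dqn/behavior: 0.57 / 0.26
```

Reading the numbers: about a third of simulated physician prescriptions
already match the model's top choice; visits that match reach the glycemic
target 3–6 months later far more often (87 % vs 55 %).  Much of that crude
gap (OR 5.3) is confounding by indication — well-controlled patients get
"no change", which the model also often ranks first — and propensity-score
weighting shrinks it to an adjusted OR of 1.46.  Patients with a higher
per-patient concordance rate accumulate fewer complications over follow-up
(negative slope), and rolling the learned policy out in the simulator
yields a higher mean per-transition clinical reward than the behavioral
(physician) policy.  The other examples cover the simulator
(`01`), the action/reward formalism (`02`) and training + recommendation
(`03`); each prints what it computes and what the numbers mean.

A thin CLI wraps the same library calls:

```bash
t2dreco simulate --n-patients 2000 --seed 1
t2dreco train --visits visits.csv --outcomes outcomes.csv --iterations 10000
t2dreco recommend --visits visits.csv --outcomes outcomes.csv \
    --model qmodel.json --scheme scheme.yaml
t2dreco evaluate-short --visits ... --model ... --scheme ...
t2dreco demo --seed 1          # full end-to-end run
```

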