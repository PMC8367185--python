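"""Train the offline dueling double-DQN on a simulated registry and emit
knowledge-gated recommendations for a held-out patient.

The pipeline is: simulate -> impute -> patient-level 80/20 split -> fit the
49-dimension feature scheme -> build (state, action, reward, next-state)
transitions -> train -> recommend with the guideline rule filter.
"""

from t2dreco.actions import enumerate_actions
from t2dreco.cohort import build_trajectories, impute_missing, split_patients
from t2dreco.dqn import TrainConfig, train
from t2dreco.featurize import fit_scheme
from t2dreco.recommend import load_rules
from t2dreco.evaluate import recommend_cohort
from t2dreco.simulate import SimulatorConfig, as_cohort, simulate_cohort

cohort = impute_missing(
    as_cohort(*simulate_cohort(SimulatorConfig(n_patients=400, seed=7)))
)
train_c, valid_c = split_patients(cohort, 0.8, seed=7)
scheme = fit_scheme(train_c)
ts = build_trajectories(train_c, "antiglycemic", scheme)
print(f"{len(ts)} training transitions, state width {scheme.width}")

model = train(
    ts.states, ts.actions, ts.rewards, ts.next_states, ts.terminal,
    n_actions=13,
    config=TrainConfig(n_iterations=2000, seed=7, conservative_weight=0.5),
    treatment_type="antiglycemic", scheme_fingerprint=scheme.fingerprint(),
)
print(f"final training loss ~ {model.loss_history[-200:].mean():.3f}")

rules = load_rules()  # treat-to-target + metformin renal-dosing rules
labels = enumerate_actions("antiglycemic").labels
recs = recommend_cohort(valid_c, model, scheme, rules, "antiglycemic")
pid = valid_c.patients()[0]
print(f"\nrecommendations for patient {pid}:")
for (p, date), rec in list(recs.items())[:6]:
    if p != pid:
        continue
    a, q, _ = rec.ranked[0]
    print(f"  {date.date()}  top-1: [{a}] {labels[a]!r}  (Q={q:.2f})")
# Q-values estimate discounted cumulative clinical reward; the rule filter
# guarantees the top-ranked action is guideline-admissible (e.g. no
# metformin in renal impairment, no 'no change' when HbA1c >= 7).
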