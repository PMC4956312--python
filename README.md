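# apctl — actor-critic insulin titration with transfer-entropy tuning

`apctl` is a research tool for **personalised daily adaptation of insulin
therapy in type-1 diabetes**. It implements a model-free Actor-Critic (AC)
reinforcement-learning controller that adjusts, once per day, the two knobs
of pump therapy — the basal rate *BR* (U/h) and the insulin:carbohydrate
ratio *IC* (U/g) — from the previous day's CGM profile, together with an
automatic per-patient initialisation of the policy from the **transfer
entropy (TE)** between the insulin and glucose signals. A built-in
minimal-model virtual patient closes the loop so the whole stack can be
exercised, tested and stress-scenarioed in silico.

## The method

**State and cost.** Each day is summarised by the glucose error
EG(t) = G−G_h above the hyperglycaemia bound (G_h = 180 mg/dl), G−G_l below
the hypoglycaemia bound (G_l = 70 mg/dl) and 0 inside the band. The MDP
state is x = [x1, x2]: the normalised mean hyper- and hypoglycaemia error
of the day, each clipped to [0, 1]. The local cost is
c(x) = a_h·x1 + a_l·x2 with a_h = 1 and a_l = 10 — avoiding hypoglycaemia
has priority.

**Critic.** The action-value of the current policy is approximated
linearly, Q(x, u) ≈ rᵀψ(x, u), with basis functions equal to the policy's
score function ψ = ∇_θ ln μ(u|x, θ). Learning is temporal-difference with
an eligibility trace:

    d  = c + γ·Q(next) − Q(prev),   r ← r + a_c·d·z,   z ← λ·z + ψ(next)

with γ = 0.9, λ = 0.5 and a starting step size a_c = 0.5 that decays as
1/√k over closed-loop days.

**Actor.** For each controlled quantity S ∈ {BR, IC}, the daily action is
the fractional change P applied as S_k = S_{k−1}(1 + P), drawn from the
Gaussian policy

    u ~ N(P_d, σ),   P_d = h·xᵀθ + (1−h)·P_s,   σ² = K_S·‖x‖²

with h = 0.5 and K_S = 0.05; P_s is a conservative supervisory rule
(±10 % of the dominant feature, hypoglycaemia taking precedence). The
policy improves by the score-function gradient, θ ← θ − β·d·ψ with
β = σ², so both exploration and learning shrink as the patient approaches
target.

**TE-based tuning.** From four days of CGM + pump data, the active insulin
IA(t) (insulin on board plus basal contribution) is estimated and the
transfer entropy from IA to glucose is computed with the fixed-partition
histogram estimator (10 mg/dl glucose bins, 1 U insulin bins, 20-min
absorption delay). The policy is initialised as
θ₀ = [W_h/TE, W_l/TE] with W_h = 0.1, W_l = −0.2: patients whose glucose
carries little information about insulin need the largest fractional
regimen updates.

## Worked example

Ten virtual subjects are started on a 40 % basal over-delivery (a
hypoglycaemia-stress scenario), observed for 4 open-loop days, then handed
to the TE-initialised controller for 10 adaptive days (5 training, 5
evaluation):

```python
import apctl

cohort = apctl.generate_cohort(apctl.CohortSpec(n_subjects=10, rng_seed=42))
scenario = apctl.Scenario(mistitration_factor=1.4)
spec = apctl.ExperimentSpec.preset("e5", seed=1)
report = apctl.run_experiment(spec, cohort, scenario)

print("open-loop phase :", {k: round(v, 2) for k, v in report.ol_cohort.items()})
print("evaluation days :", {k: round(v, 2) for k, v in report.cohort.items()})
s0 = report.per_subject.iloc[0]
print(f"subject 0: TE = {s0.te:.3f} bits, LBGI {s0.ol_lbgi:.2f} -> {s0.lbgi:.2f}")
```

prints

```
open-loop phase : {'pct_target': 61.58, 'pct_mild_hypo': 36.02, 'pct_severe_hypo': 2.4, 'pct_mild_hyper': 0.0, 'pct_severe_hyper': 0.0, 'lbgi': 7.72}
evaluation days : {'pct_target': 99.01, 'pct_mild_hypo': 0.07, 'pct_severe_hypo': 0.0, 'pct_mild_hyper': 0.92, 'pct_severe_hyper': 0.0, 'lbgi': 0.23, 'n_subjects': 10, 'n_failed': 0}
subject 0: TE = 0.099 bits, LBGI 5.60 -> 0.35
```

Under open loop the cohort spends 38 % of the time below 70 mg/dl with a
Low Blood Glucose Index (LBGI) of 7.7; after five days of training the
controller has re-titrated both BR and IC so that hypoglycaemia essentially
disappears (0.07 % of time) while time in the 70–180 mg/dl target range
rises from 62 % to 99 %.

The same trials are available from the shell:

```bash
apctl cohort --n 10 --seed 42 --mistitration 1.4 --out cohort.json
apctl run --preset e5 --cohort cohort.json --seed 1 --out results/e5
apctl te --glucose glucose.csv --pump pump.csv --out te.json
apctl report --runs results --out summary.csv
```

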