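# Methods

This note documents the models, parameters and numerical choices behind
`apctl`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Daily featurisation and cost

A day of CGM data (5-min grid, 288 samples) is reduced to the state
x = [x1, x2] of mean hyper- and hypoglycaemia error. Two statistics are
available:

* **Mean excursion magnitude** (default): x_i is the mean of |EG| over the
  samples outside the band on that side, zero when there are none. This is
  the "average daily error" reading of the feature definition.
* **Indicator mean** (`indicator_mean=True`): the literal average of the
  Heaviside indicator over excursion samples, which is identically 0 or 1.
  Retained only for fidelity comparisons; it discards excursion depth and
  is not used by default.

Normalisation is by fixed physiologic scales rather than per-patient
statistics: hyper scale 120 mg/dl (300 − 180) and hypo scale 30 mg/dl
(70 − 40), then clipping to [0, 1]. A day pinned at the severe bounds
(300 or 40 mg/dl) maps to a feature of 1; the scales are configurable
(`FeatureScale`). The local cost is c = a_h·x1 + a_l·x2 with defaults
a_h = 1, a_l = 10 (hypoglycaemia priority); both weights configurable.

## Critic

One Critic per controlled quantity (basal rate, IC ratio) by default; a
shared-Critic mode exists (`shared_critic=True`) since either reading is
defensible. Parameters: γ = 0.9, λ = 0.5, r₀ ~ U[−1, 1] from the run's
seeded generator, z₀ = 0.

The update order is fixed and tested: the parameter step uses the
eligibility as accumulated **up to** the transition (r ← r + a·d·z), then
the trace decays and absorbs the next feature vector (z ← λz + ψ(next)).
The trace decays by λ alone. With tabular features the fixed point is the
true discounted action-value for any λ, which the test suite verifies
against a matrix-inversion oracle on a 2-state/2-action chain (within 2 %
after 10⁴ transitions with a 1/k-decaying step size).

Because the TD error is written for a state-value function but only the
action-value is ever approximated (with features φ = ψ), the implemented
form is SARSA-style: d = c + γ·rᵀψ(next state, next action) − rᵀψ(prev).
The cost entering a transition is that of the state in which the action
was taken.

**Step-size schedule.** The TD update is defined for a positive
non-increasing learning-rate sequence with starting value 0.5. A constant
0.5 is unstable here: the score-function features have squared norm
concentrating at h²/K_S = 5 (because ψ ∝ x/σ and σ ∝ ‖x‖), which exceeds
the 2/a stability margin of constant-step linear TD; in extended runs the
TD error then grows without bound. The daily loop therefore decays the
Critic step as a_k = 0.5/√k over closed-loop days
(`critic_lr_decay="rsqrt"`; `"none"` restores the constant for ablation).

## Actor

For each quantity the day's action is the fractional change
S_k = S_{k−1}(1 + P). The applied action is Gaussian around the blended
deterministic action P_d = h·xᵀθ + (1−h)·P_s, h = 0.5. The supervisory
action P_s is ±0.1 times the dominant feature; when both features are
positive the hypoglycaemia branch wins (the safety-relevant reading of the
rule's precedence).

**Sign convention for IC.** With IC in U/g, more insulin per gram corrects
hyperglycaemia, so by default both quantities respond to hyperglycaemia
with a positive (insulin-increasing) change. The opposite-sign convention
for the IC supervisor — consistent with reading the ratio as grams per
unit — is available via `ic_opposite_sign=True`.

Exploration: σ² = K_S·‖x‖² with K_S = 0.05, floored at σ_min = 10⁻³ so the
density and the score ψ = ((u − P_d)/σ²)·h·x remain well defined at zero
state (ψ divides by σ²). The Actor learning rate is β = σ² (a
constant-rate mode exists for ablation), evaluated at the transition being
credited, and the update is θ ← θ − β·d·ψ(prev). At x = 0 the policy is
degenerate at zero change: a patient at target receives no regimen update
in expectation.

Safety bounds (artifact policy, not part of the learning math): basal
∈ [0.05, 5] U/h, IC ∈ [0.01, 0.5] U/g, |P| capped at 0.3 per day; all
configurable, every cap/clamp logged in the decision log.

Exploration noise is drawn independently per controlled quantity per day;
one stream per subject, spawned from the experiment seed.

## Transfer-entropy tuning

Active insulin IA(t) = bolus insulin-on-board + basal contribution, on the
CGM grid. The IOB curve is a **linear** remaining-fraction over a 4-h
action duration by default; a bi-exponential alternative
((1 + t/τ)e^{−t/τ}, τ = duration/5, truncated at the duration) is
selectable. The basal term treats the infusion as a train of per-sample
micro-boluses through the same curve, assuming the pump ran at its initial
rate before the record starts (so constant basal ⇒ constant IA ≈ rate ×
half the action duration); an "instantaneous" rate×interval mode exists.

TE is the plug-in estimate of
Σ p(G_t, G_{t−1}, IA_{t−d}) log₂ [p(G_t|G_{t−1}, IA_{t−d}) / p(G_t|G_{t−1})]
with fixed-width right-open histogram bins anchored at 0 (glucose 10
mg/dl, insulin 1 U), the delay d = 20 min applied as an index shift, and
first-order glucose history only (no embedding search). Output is in bits.
Estimates are clipped at zero; a single-bin glucose series returns 0 with
a warning. Initialisation: θ₀ = [W_h/TE, W_l/TE], W_h = 0.1, W_l = −0.2;
below a floor of 10⁻³ bits the ratio would explode, so the system falls
back to zero initialisation (the manual mode) with a logged warning.

## Virtual patient

The environment is an original minimal-model-class ODE system — the
smallest documented model exhibiting the delays and sensitivities a daily
titration controller must cope with (it does not attempt to reproduce any
full-scale simulator numerically):

* two subcutaneous insulin compartments (τ_i ≈ 10 min each, ~20-min
  effective absorption delay);
* remote insulin action X (first-order, rate p2), scaled by the diurnally
  modulated insulin sensitivity;
* one glucose compartment with two classical insulin channels:
  mass-action peripheral uptake, −(p1 + X/100)·G, and linear suppression
  of endogenous glucose production, EGP(X) = EGP₀·max(0, 1 − X/X₅₀) with
  X₅₀ = 3 × the equilibrium action. Uptake scaling makes deep
  hypoglycaemia self-limiting; EGP suppression is what makes sustained
  basal over-delivery genuinely hypoglycaemic. EGP₀ is solved per patient
  so glucose rests at `basal_glucose` under the equilibrium basal;
* a two-compartment gut model (appearance peak at τ_m, mass conserved to
  the bioavailable fraction).

Integration is fixed-step Heun at 1 min (halving the step changes a
24-h trace by < 0.5 mg/dl); impulses (boluses, meals) enter at the start
of their step. Glucose is floored at 20 mg/dl and hitting the floor flags
the subject as a simulation failure; failed subjects are excluded from
cohort metrics but always listed in reports.

Default cohort ranges were calibrated once against physiological dose
response — doubling the basal rate lowers fasting glucose by roughly
50–90 mg/dl across the ranges — so that the ×1.4 basal stress scenario
produces substantial but recoverable hypoglycaemia (cohort ~38 % of time
< 70 mg/dl, no floor hits), while a well-titrated open loop stays ~90 % in
target with ~10 % mild hypoglycaemia driven by the ±50 % carb-counting
error. `mixed_cohort_spec` widens the ranges (children through adults:
distribution volume 45–180 dl, basal need 0.3–2 U/h, sensitivity 18–60) for
heterogeneity studies such as the TE window analysis.

The SI schedule lowers sensitivity 25 % between 04:00 and 08:00 daily
(30-min linear ramps inside the window) and raises it 33 % between 18:00
and 20:00 on exercise days (30-min ramp up, 4-h ramp down), with exercise
fixed on days 1, 3, 5 of each simulated week for reproducibility; effects
compose multiplicatively. Meals default to 50/70/60 g at 07:00/13:00/19:00,
announced 30 min before intake with uniform ±50 % error; the bolus
(IC × announced grams) is delivered at intake by default
(announcement-time delivery selectable). CGM output is noise-free (an
optional sensor-noise flag is deliberately absent from all default and
acceptance paths); sampling is 5 min.

**What the generator does not emulate:** CGM sensor error and dropouts,
counter-regulatory (glucagon) response, exercise-induced glucose uptake
beyond the SI multiplier, multi-segment basal profiles, and the richer
inter-subject covariance of full-scale metabolic simulators. Passing tests
therefore demonstrate correctness of the learning and estimation machinery
and qualitative closed-loop behaviour, not clinical performance.

## Experiment designs and metrics

Presets E1–E6: open loop without/with SI variation (E1/E2); closed loop
with zero θ₀ (E3/E4); closed loop with TE-based θ₀ computed from the
trial's own 4 open-loop days (E5/E6). A standard trial is 4 OL days + 10
CL days, the first 5 CL days training and the last 5 the evaluation
window; extended convergence runs use 26 CL days (30 in total).

Metrics use closed target [70, 180] mg/dl, mild hypo [50, 70), severe
hypo < 50, mild hyper (180, 300], severe hyper > 300; the five percentages
sum to 100 per subject. LBGI is the mean of 10·f(G)² over samples with
f(G) = 1.509(ln(G)^1.084 − 5.381) < 0; f crosses zero at ≈ 112.52 mg/dl,
so traces wholly above that level score exactly 0.

`convergence_check` flags a policy parameter as settled when its trailing
10-day range is below 5 % of max(|mean|, 1.0); the absolute floor of 1.0
(the natural scale of θ) keeps the criterion meaningful for parameters
resting near zero.

Stochastic cohort-level claims are evaluated as medians over ≥ 5 seeds.

## Known limitations

* The TE estimator's window-to-window sampling noise (sd ≈ 0.008 bits at
  4–5 days of 5-min data) against a between-subject spread of ≈ 0.04–0.05
  bits bounds the subject-wise 4- vs 5-day correlation near 0.98–0.99 in
  this environment; the correlation rises monotonically with window
  length, but the strictest stability threshold in the acceptance suite
  (0.99) sits at the edge of what this data length supports.
* In this environment TE mostly tracks the absolute insulin mass against
  the fixed 1-U partition: at matched total daily insulin, varying
  sensitivity alone leaves TE nearly flat, because the mass-action uptake
  term (∝ X·G) self-compensates — a low-sensitivity patient runs higher
  glucose, restoring the per-unit effect. The initialisation θ₀ ∝ 1/TE
  still confers a robust benefit (larger safe steps where the data are
  least informative), but the clean SI ↔ TE correspondence should not be
  read off these simulations.
* Zero-initialised closed loop on a strongly mis-titrated cohort can drift
  before it learns (exploration noise dominates the weak supervisory
  drift); this is visible in the tuning-benefit comparisons and is the
  behaviour the TE initialisation is designed to fix.
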