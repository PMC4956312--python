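"""Experiment orchestration: open-/closed-loop trials, metrics, reports.

Reproduces the six-experiment design over a synthetic cohort:

* E1/E2 — open loop (OL): the subject's standard regimen held fixed,
  without/with diurnal insulin-sensitivity (SI) variation.
* E3/E4 — closed loop (CL): the actor-critic controller with zero policy
  initialisation, without/with SI variation.
* E5/E6 — closed loop with transfer-entropy-based policy initialisation
  computed from the trial's own OL days, without/with SI variation.

A trial runs ``ol_days`` of standard treatment followed by ``cl_days`` of
daily adaptation; the first ``training_days`` CL days are the training
phase and the remainder the evaluation window for all reported metrics.
Every random draw descends from the experiment seed, so a run replays
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import actor as act
from . import critic as cr
from . import glycemic_state as gs
from . import tuning as tn
from . import virtual_patient as vp

__all__ = [
    "ExperimentSpec",
    "Scenario",
    "EvaluationReport",
    "time_in_ranges",
    "lbgi",
    "run_experiment",
    "convergence_check",
    "write_report",
]

RANGE_NAMES = ("target", "mild_hypo", "severe_hypo", "mild_hyper", "severe_hyper")


@dataclass(frozen=True)
class Scenario:
    """Meal protocol and open-loop titration of a trial.

    Default protocol: three daily meals of 50/70/60 g carbohydrate at
    07:00, 13:00 and 19:00, announced 30 min before intake with uniform
    +/-50% carbohydrate-counting error.  ``mistitration_factor`` scales the
    standard open-loop basal rate (> 1 over-delivers insulin and stresses
    the cohort toward hypoglycaemia).
    """

    meal_times: tuple = (7 * 60.0, 13 * 60.0, 19 * 60.0)
    meal_chos: tuple = (50.0, 70.0, 60.0)
    meal_uncertainty: float = 0.5
    announcement_lead: float = 30.0
    mistitration_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.meal_times) != len(self.meal_chos):
            raise ValueError("meal_times and meal_chos must pair up")
        if not (0 <= self.meal_uncertainty < 1):
            raise ValueError("meal_uncertainty must be in [0, 1)")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


_PRESETS = {
    "e1": dict(mode="open-loop", si_variation=False, te_init=False),
    "e2": dict(mode="open-loop", si_variation=True, te_init=False),
    "e3": dict(mode="closed-loop", si_variation=False, te_init=False),
    "e4": dict(mode="closed-loop", si_variation=True, te_init=False),
    "e5": dict(mode="closed-loop", si_variation=False, te_init=True),
    "e6": dict(mode="closed-loop", si_variation=True, te_init=True),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One trial design.

    A 14-day standard trial is 4 OL days plus 10 CL days, of which the
    first 5 are training and the last 5 evaluation; extended convergence
    runs stretch ``cl_days`` (e.g. 26 for a 30-day trial).
    """

    mode: str = "closed-loop"  # "open-loop" | "closed-loop"
    ol_days: int = 4
    cl_days: int = 10
    training_days: int = 5
    si_variation: bool = False
    te_init: bool = False
    meal_uncertainty: float | None = None  # None -> scenario value
    seed: int = 0
    shared_critic: bool = False
    ic_opposite_sign: bool = False
    bolus_at_announcement: bool = False
    # Critic step-size schedule over CL days: the TD update is defined for a
    # non-increasing learning-rate sequence; the default 1/sqrt(k) decay from
    # the 0.5 starting value keeps the constant-step feature norms stable.
    critic_lr_decay: str = "rsqrt"  # "rsqrt" | "none"

    def __post_init__(self) -> None:
        if self.mode not in ("open-loop", "closed-loop"):
            raise ValueError("mode must be 'open-loop' or 'closed-loop'")
        if self.ol_days < 0 or self.cl_days < 0 or self.training_days < 0:
            raise ValueError("day counts must be non-negative")
        if self.mode == "closed-loop" and self.training_days > self.cl_days:
            raise ValueError("training_days cannot exceed cl_days")

    @classmethod
    def preset(cls, name: str, *, seed: int = 0, **overrides) -> "ExperimentSpec":
        """E1..E6 presets; open-loop presets have no CL days."""
        name = name.lower()
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}")
        kw = dict(_PRESETS[name])
        if kw["mode"] == "open-loop":
            kw.setdefault("cl_days", 0)
            kw.setdefault("training_days", 0)
        kw.update(overrides, seed=seed)
        return cls(**kw)


def time_in_ranges(trace: gs.GlucoseTrace) -> np.ndarray:
    """Percent of samples in [target, mild hypo, severe hypo, mild hyper, severe hyper].

    Boundary conventions: target is the closed interval [70, 180] mg/dl,
    mild hypoglycaemia [50, 70), severe hypoglycaemia < 50, mild
    hyperglycaemia (180, 300], severe hyperglycaemia > 300.
    """
    g = trace.values
    n = g.size
    target = np.count_nonzero((g >= 70) & (g <= 180))
    mild_hypo = np.count_nonzero((g >= 50) & (g < 70))
    severe_hypo = np.count_nonzero(g < 50)
    mild_hyper = np.count_nonzero((g > 180) & (g <= 300))
    severe_hyper = np.count_nonzero(g > 300)
    return 100.0 * np.array(
        [target, mild_hypo, severe_hypo, mild_hyper, severe_hyper]
    ) / n


def lbgi(trace: gs.GlucoseTrace) -> float:
    """Low Blood Glucose Index: mean hypoglycaemic risk of the trace.

    The symmetrised risk transform f(G) = 1.509*(ln(G)^1.084 - 5.381)
    crosses zero near 112.5 mg/dl; samples below contribute rl = 10*f^2 and
    the LBGI is the mean of rl over all samples.
    """
    g = trace.values
    if np.any(g <= 0):
        raise ValueError("glucose must be positive for the risk transform")
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    rl = np.where(f < 0, 10.0 * f**2, 0.0)
    return float(rl.mean())


@dataclass(frozen=True)
class EvaluationReport:
    """Results of one experiment run.

    ``per_subject`` holds evaluation-window range percentages, LBGI and
    failure flags per subject; ``cohort`` is the mean over non-failed
    subjects; ``daily_lbgi`` is the day-by-subject LBGI matrix over the
    whole trial; ``decision_log`` records every daily controller decision;
    ``ol_cohort`` are the same range metrics over the OL phase for
    comparison.
    """

    per_subject: pd.DataFrame
    cohort: dict
    ol_cohort: dict
    daily_lbgi: pd.DataFrame
    decision_log: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _daily_metrics(traces: list[gs.GlucoseTrace]) -> tuple[np.ndarray, float]:
    """Range percentages (pooled over days) and mean daily LBGI."""
    pooled = gs.GlucoseTrace(
        np.concatenate([t.values for t in traces]),
        start_time=traces[0].start_time,
        sampling_interval=traces[0].sampling_interval,
    )
    return time_in_ranges(pooled), float(np.mean([lbgi(t) for t in traces]))


def _make_meals(scenario: Scenario, uncertainty: float, rng) -> list[vp.MealEvent]:
    return [
        vp.announce_meal(t, cho, uncertainty, rng, lead=scenario.announcement_lead)
        for t, cho in zip(scenario.meal_times, scenario.meal_chos)
    ]


class _Controller:
    """Daily actor-critic state for one subject (both controlled quantities)."""

    def __init__(
        self,
        theta0: act.PolicyParameters,
        rng: np.random.Generator,
        spec: ExperimentSpec,
        cfg: act.ExplorationConfig,
        weights: gs.CostWeights,
        bounds: act.RegimenBounds,
    ):
        self.spec = spec
        self.cfg = cfg
        self.weights = weights
        self.bounds = bounds
        self.rng = rng
        self.theta = {"BR": theta0, "IC": theta0}
        shared = cr.CriticState.initialise(2, rng)
        self.critic = {
            "BR": shared,
            "IC": shared if spec.shared_critic else cr.CriticState.initialise(2, rng),
        }
        self.prev: dict[str, tuple | None] = {"BR": None, "IC": None}
        self.base_lr = {n: self.critic[n].learning_rate for n in ("BR", "IC")}
        self.n_updates = 0

    def decide(
        self, day: int, x: gs.StateFeatures, regimen: act.InsulinRegimen
    ) -> tuple[act.InsulinRegimen, list[dict]]:
        """Consume yesterday's state, learn, and emit the next regimen."""
        cost = gs.local_cost(x, self.weights)
        rows = []
        actions = {}
        for name in ("BR", "IC"):
            theta = self.theta[name]
            critic = self.critic[name]
            pa = act.deterministic_action(x, theta)
            ps = act.supervisory_action(
                x, name, ic_opposite_sign=self.spec.ic_opposite_sign
            )
            pd_ = act.total_deterministic(pa, ps, self.cfg.h)
            sigma = act.exploration_sigma(x, self.cfg)
            u = act.sample_action(pd_, sigma, self.rng)
            psi = act.likelihood_ratio_derivative(
                u, pd_, sigma, self.cfg.h * x.as_array()
            )
            value_next = cr.approx_action_value(critic, psi)
            td = np.nan
            if self.prev[name] is not None:
                psi_prev, sigma_prev, cost_prev = self.prev[name]
                value_prev = cr.approx_action_value(critic, psi_prev)
                td = cr.td_error(cost_prev, value_prev, value_next, critic.gamma)
                if self.spec.critic_lr_decay == "rsqrt":
                    lr = self.base_lr[name] / np.sqrt(self.n_updates + 1)
                    critic = dc_replace(critic, learning_rate=lr)
                critic = cr.critic_update(critic, td, psi)
                theta = act.actor_update(theta, td, psi_prev, sigma_prev**2)
            else:
                # seed the eligibility with the first observed features
                critic = cr.critic_update(critic, 0.0, psi)
            self.prev[name] = (psi, sigma, cost)
            self.theta[name] = theta
            self.critic[name] = critic
            actions[name] = u
            rows.append(
                {
                    "day": day,
                    "controlled": name,
                    "x1": x.x1,
                    "x2": x.x2,
                    "pa": pa,
                    "ps": ps,
                    "pd": pd_,
                    "pe": u,
                    "sigma": sigma,
                    "td_error": td,
                    "theta1": theta.theta[0],
                    "theta2": theta.theta[1],
                }
            )
        self.n_updates += 1
        new_regimen, clamped = act.apply_regimen_update(
            regimen, actions["BR"], actions["IC"], self.bounds
        )
        for row in rows:
            row["S_before"] = (
                regimen.basal_rate if row["controlled"] == "BR" else regimen.ic_ratio
            )
            row["S_after"] = (
                new_regimen.basal_rate
                if row["controlled"] == "BR"
                else new_regimen.ic_ratio
            )
            row["clamped"] = clamped
        return new_regimen, rows


def run_experiment(
    spec: ExperimentSpec,
    cohort: list[vp.PatientParameters],
    scenario: Scenario = Scenario(),
    *,
    exploration: act.ExplorationConfig = act.ExplorationConfig(),
    cost_weights: gs.CostWeights = gs.CostWeights(),
    bounds: act.RegimenBounds = act.RegimenBounds(),
    te_config: tn.TEConfig = tn.TEConfig(),
    theta_weights: tn.ThetaInitWeights = tn.ThetaInitWeights(),
    keep_traces: bool = False,
) -> EvaluationReport:
    """Run one experiment over a cohort and compute the evaluation report.

    OL days apply the subject's standard (possibly mis-titrated) regimen.
    For closed loop with ``te_init``, transfer entropy is estimated from the
    subject's own OL glucose and pump data and the policy vector
    initialised from it; the daily loop then featurises the previous day,
    updates Critic and Actor, and applies the new regimen.  Subjects whose
    glucose hits the simulation floor are flagged as failed, excluded from
    cohort means but always listed.
    """
    uncertainty = (
        scenario.meal_uncertainty
        if spec.meal_uncertainty is None
        else spec.meal_uncertainty
    )
    schedule = vp.SISchedule(enabled=spec.si_variation)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(cohort))
    subject_rows = []
    lbgi_cols = {}
    log_rows = []
    all_traces: dict[int, list] = {}
    for sid, (patient, ss) in enumerate(zip(cohort, seeds)):
        rng = np.random.default_rng(ss)
        standard = vp.standard_regimen(patient, scenario.mistitration_factor)
        regimen = standard
        # trial starts from the subject's well-controlled equilibrium
        state = vp.steady_state(patient, patient.equilibrium_basal)
        failed = False
        traces, pumps = [], []
        controller = None
        te_value = np.nan
        day = 0
        for _ in range(spec.ol_days):
            meals = _make_meals(scenario, uncertainty, rng)
            res = vp.run_day(
                patient,
                regimen,
                meals,
                schedule,
                day_index=day,
                initial_state=state,
                bolus_at_announcement=spec.bolus_at_announcement,
            )
            state = res.end_state
            failed |= res.failed
            traces.append(res.trace)
            pumps.append(res.pump)
            day += 1
        n_ol = len(traces)
        if spec.mode == "closed-loop":
            theta0 = act.PolicyParameters.zeros()
            if spec.te_init and traces:
                glu = gs.GlucoseTrace(
                    np.concatenate([t.values for t in traces]),
                    start_time=traces[0].start_time,
                    sampling_interval=traces[0].sampling_interval,
                )
                pump = tn.PumpRecord(
                    basal_series=np.concatenate([p.basal_series for p in pumps]),
                    bolus_events=tuple(
                        (d * gs.MINUTES_PER_DAY + t, u)
                        for d, p in enumerate(pumps)
                        for t, u in p.bolus_events
                    ),
                    sampling_interval=glu.sampling_interval,
                    start_time=glu.start_time,
                )
                ia = tn.active_insulin(pump, glu, te_config)
                te_value = tn.transfer_entropy(glu, ia, te_config)
                theta0 = tn.initialize_theta(te_value, theta_weights)
            controller = _Controller(
                theta0, rng, spec, exploration, cost_weights, bounds
            )
            for _ in range(spec.cl_days):
                meals = _make_meals(scenario, uncertainty, rng)
                res = vp.run_day(
                    patient,
                    regimen,
                    meals,
                    schedule,
                    day_index=day,
                    initial_state=state,
                    bolus_at_announcement=spec.bolus_at_announcement,
                )
                state = res.end_state
                failed |= res.failed
                traces.append(res.trace)
                pumps.append(res.pump)
                x = gs.daily_features(res.trace)
                regimen, rows = controller.decide(day, x, regimen)
                for row in rows:
                    row["subject"] = sid
                log_rows.extend(rows)
                day += 1
        # metrics
        eval_start = (
            n_ol + spec.training_days if spec.mode == "closed-loop" else 0
        )
        eval_traces = traces[eval_start:] if traces[eval_start:] else traces
        ranges, mean_lbgi = _daily_metrics(eval_traces)
        ol_ranges, ol_lbgi = (
            _daily_metrics(traces[:n_ol]) if n_ol else (np.full(5, np.nan), np.nan)
        )
        row = {"subject": sid, "failed": failed, "te": te_value, "lbgi": mean_lbgi}
        row.update({f"pct_{n}": v for n, v in zip(RANGE_NAMES, ranges)})
        row.update({f"ol_pct_{n}": v for n, v in zip(RANGE_NAMES, ol_ranges)})
        row["ol_lbgi"] = ol_lbgi
        subject_rows.append(row)
        lbgi_cols[sid] = [lbgi(t) for t in traces]
        if keep_traces:
            all_traces[sid] = traces
    per_subject = pd.DataFrame(subject_rows)
    ok = per_subject[~per_subject["failed"]]
    cohort_mean = (
        {
            f"pct_{n}": float(ok[f"pct_{n}"].mean()) for n in RANGE_NAMES
        }
        | {"lbgi": float(ok["lbgi"].mean()), "n_subjects": int(len(per_subject)),
           "n_failed": int(per_subject["failed"].sum())}
        if len(ok)
        else {"n_subjects": int(len(per_subject)), "n_failed": int(len(per_subject))}
    )
    ol_cohort = (
        {f"pct_{n}": float(ok[f"ol_pct_{n}"].mean()) for n in RANGE_NAMES}
        | {"lbgi": float(ok["ol_lbgi"].mean())}
        if len(ok) and spec.ol_days
        else {}
    )
    daily_lbgi = pd.DataFrame(lbgi_cols)
    daily_lbgi.index.name = "day"
    decision_log = pd.DataFrame(log_rows)
    meta = {
        "spec": asdict(spec),
        "scenario": asdict(scenario),
        "config_hash": hashlib.sha256(
            json.dumps(
                {"spec": asdict(spec), "scenario": asdict(scenario)},
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
    }
    report = EvaluationReport(
        per_subject=per_subject,
        cohort=cohort_mean,
        ol_cohort=ol_cohort,
        daily_lbgi=daily_lbgi,
        decision_log=decision_log,
        metadata=meta,
    )
    if keep_traces:
        object.__setattr__(report, "traces", all_traces)
    return report


def convergence_check(
    decision_log: pd.DataFrame,
    window: int = 10,
    tol: float = 0.05,
    theta_scale: float = 1.0,
) -> pd.DataFrame:
    """Flag policy parameters whose trailing-window range has settled.

    For each (subject, controlled quantity, parameter), the last ``window``
    logged days are examined; the parameter is stable when its range
    (max - min) is below ``tol`` times max(|mean|, theta_scale).  The
    absolute floor ``theta_scale`` keeps the test meaningful for parameters
    resting near zero.
    """
    if decision_log.empty:
        raise ValueError("empty decision log")
    n_days = decision_log["day"].nunique()
    if n_days < window:
        raise ValueError(f"log spans {n_days} days < window {window}")
    rows = []
    for (sid, name), grp in decision_log.groupby(["subject", "controlled"]):
        tail = grp.sort_values("day").tail(window)
        for param in ("theta1", "theta2"):
            v = tail[param].to_numpy()
            rng_ = float(v.max() - v.min())
            denom = max(abs(float(v.mean())), theta_scale)
            rows.append(
                {
                    "subject": sid,
                    "controlled": name,
                    "parameter": param,
                    "range": rng_,
                    "relative_range": rng_ / denom,
                    "stable": rng_ / denom < tol,
                }
            )
    return pd.DataFrame(rows)


def write_report(report: EvaluationReport, outdir) -> None:
    """Write the report as plain CSV/JSON files under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_subject.to_csv(out / "per_subject.csv", index=False)
    report.daily_lbgi.to_csv(out / "daily_lbgi.csv")
    if not report.decision_log.empty:
        report.decision_log.to_csv(out / "decision_log.csv", index=False)
    with open(out / "cohort.json", "w") as fh:
        json.dump(
            {
                "cohort": report.cohort,
                "ol_cohort": report.ol_cohort,
                "metadata": report.metadata,
            },
            fh,
            indent=2,
        )
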