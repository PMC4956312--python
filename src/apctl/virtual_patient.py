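"""Synthetic closed-loop glucose-insulin environment.

A minimal-model-class virtual patient used to exercise the controller in
place of a full-scale metabolic simulator.  The dynamics are deliberately
the smallest documented system exhibiting the delays and sensitivities a
daily regimen controller must cope with:

* two subcutaneous insulin compartments (first-order cascade, time constant
  ``sc_absorption_time``, giving a ~20-min effective absorption delay),
* a remote insulin-action state X driven by the plasma insulin delivery
  rate and scaled by the (diurnally modulated) insulin sensitivity,
* one glucose compartment relaxing toward an endogenous balance point at
  rate ``glucose_effectiveness`` and lowered by X,
* a two-compartment gut model turning carbohydrate into a glucose rate of
  appearance with peak at ``meal_time_to_peak``.

With the state vector s = (Isc1, Isc2, X, G, Q1, Q2) and insulin delivery
u(t) in U/min, carbohydrate input D(t) in g:

    dIsc1/dt = u - Isc1/tau_i                 [U]
    dIsc2/dt = (Isc1 - Isc2)/tau_i            [U]
    dX/dt    = p2 * (SI_eff * Isc2/tau_i - X) [mg/dl/min at 100 mg/dl]
    dG/dt    = -(p1 + X/100) * G + EGP(X) + Ra*1000*f/Vd
    dQ1/dt   = D - Q1/tau_m                   [g]
    dQ2/dt   = (Q1 - Q2)/tau_m,  Ra = Q2/tau_m

Insulin acts through two classical channels.  Peripheral uptake is
multiplicative in glucose (mass action): X is the insulin-mediated
fractional clearance expressed as mg/dl/min at the 100 mg/dl reference,
so its effect shrinks as glucose falls.  Endogenous glucose production is
linearly suppressed by insulin action,

    EGP(X) = EGP0 * max(0, 1 - X / X50),   X50 = egp_suppression * X_eq,

vanishing when action reaches ``egp_suppression`` times the equilibrium
action X_eq; this is what makes sustained basal over-delivery genuinely
hypoglycaemic while uptake scaling keeps the fall self-limiting.  EGP0 is
fixed per patient so glucose rests exactly at ``basal_glucose`` under the
equilibrium basal rate at nominal insulin sensitivity.  Integration is
fixed-step Heun (explicit trapezoidal) at <= 1 min; boluses and meals
enter as impulses at the start of their step.

Glucose is floored at 20 mg/dl; hitting the floor flags the subject as a
simulation failure (such subjects are excluded from cohort metrics but
always listed, mirroring how non-recoverable subjects are handled in
in-silico trial reporting).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .actor import InsulinRegimen, bolus_from_meal
from .glycemic_state import GlucoseTrace, MINUTES_PER_DAY
from .tuning import PumpRecord

__all__ = [
    "PatientParameters",
    "SISchedule",
    "MealEvent",
    "CohortSpec",
    "DayResult",
    "GLUCOSE_FLOOR",
    "si_multiplier",
    "step",
    "announce_meal",
    "standard_regimen",
    "generate_cohort",
    "run_day",
    "save_cohort",
    "load_cohort",
]

GLUCOSE_FLOOR = 20.0  # mg/dl; reaching it marks the subject as failed
CGM_INTERVAL = 5.0  # min
SIM_DT = 1.0  # min


@dataclass(frozen=True)
class PatientParameters:
    """One synthetic subject of the minimal-model environment."""

    basal_glucose: float = 120.0  # mg/dl fasting target under equilibrium basal
    glucose_effectiveness: float = 0.005  # p1, 1/min (insulin-independent clearance)
    si_nominal: float = 36.0  # mg/dl/min lowering per U/min delivered, at 100 mg/dl
    insulin_action_rate: float = 0.012  # p2, 1/min
    sc_absorption_time: float = 10.0  # tau_i, min per compartment (~20 min delay)
    distribution_volume: float = 120.0  # Vd, dl
    meal_time_to_peak: float = 40.0  # tau_m, min
    meal_bioavailability: float = 0.8
    weight: float = 70.0  # kg
    tdi_reference: float = 40.0  # U/day, bookkeeping only
    equilibrium_basal: float = 1.0  # U/h holding G at basal_glucose at nominal SI
    egp_suppression: float = 3.0  # EGP vanishes at this multiple of equilibrium action

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all patient parameters must be positive")
        if not (0 < self.meal_bioavailability <= 1):
            raise ValueError("meal_bioavailability must be in (0, 1]")

    @property
    def equilibrium_action(self) -> float:
        """Insulin action X_eq under the equilibrium basal at nominal SI."""
        return self.si_nominal * self.equilibrium_basal / 60.0

    @property
    def endogenous_input(self) -> float:
        """Unsuppressed endogenous glucose production EGP0 (mg/dl/min).

        Chosen so that, with EGP partially suppressed at the equilibrium
        action, production balances total clearance (p1 + X_eq/100)*Gb.
        """
        x_eq = self.equilibrium_action
        suppressed = 1.0 - 1.0 / self.egp_suppression
        return (
            (self.glucose_effectiveness + x_eq / 100.0)
            * self.basal_glucose
            / suppressed
        )

    def egp(self, x: float) -> float:
        """Endogenous glucose production at insulin action ``x``, mg/dl/min."""
        x50 = self.egp_suppression * self.equilibrium_action
        return self.endogenous_input * max(0.0, 1.0 - x / x50)

    def equilibrium_ic_ratio(self) -> float:
        """IC ratio (U/g) approximately covering a meal's integrated appearance.

        Balancing the integrated glucose raise f*cho*1000/Vd against the
        integrated insulin action at the fasting operating point,
        B*SI*Gb/100, gives B/cho = f*1000*100/(Vd*SI*Gb).
        """
        return self.meal_bioavailability * 1000.0 * 100.0 / (
            self.distribution_volume * self.si_nominal * self.basal_glucose
        )


@dataclass(frozen=True)
class SISchedule:
    """Diurnal insulin-sensitivity multipliers: dawn drop and exercise rise.

    The dawn phenomenon lowers SI by 25% between 04:00 and 08:00; on
    exercise days SI rises by 33% between 18:00 and 20:00.  Transitions are
    linear: 30-min ramps into and out of the dawn window, a 30-min ramp up
    at exercise start and a 4-h ramp down after it ends.  Exercise falls on
    days 1, 3 and 5 of each simulated week.
    """

    dawn_drop: float = -0.25
    dawn_start: float = 4 * 60.0  # minutes of day
    dawn_end: float = 8 * 60.0
    dawn_ramp: float = 30.0
    exercise_gain: float = 0.33
    exercise_start: float = 18 * 60.0
    exercise_end: float = 20 * 60.0
    exercise_ramp_up: float = 30.0
    exercise_ramp_down: float = 240.0
    exercise_days: tuple = (0, 2, 4)  # day-of-week indices (day 1, 3, 5)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.dawn_ramp < 0 or self.exercise_ramp_up < 0 or self.exercise_ramp_down < 0:
            raise ValueError("ramps must be non-negative")
        for t in (self.dawn_start, self.dawn_end, self.exercise_start, self.exercise_end):
            if not (0 <= t <= MINUTES_PER_DAY):
                raise ValueError("schedule windows must lie within the day")


def _ramp_profile(
    t: float, start: float, end: float, ramp_in: float, ramp_out: float
) -> float:
    """Trapezoid in [0,1]: ramps up over [start, start+ramp_in], holds, ramps down over [end, end+ramp_out]."""
    if t < start or t >= end + ramp_out:
        return 0.0
    if t < start + ramp_in:
        return (t - start) / ramp_in if ramp_in > 0 else 1.0
    if t < end:
        return 1.0
    return 1.0 - (t - end) / ramp_out if ramp_out > 0 else 0.0


def si_multiplier(schedule: SISchedule, t_of_day: float, day_index: int) -> float:
    """Piecewise-linear SI multiplier at minute ``t_of_day`` of day ``day_index``.

    Dawn and exercise effects compose multiplicatively if their windows
    ever overlap.
    """
    if not schedule.enabled:
        return 1.0
    # dawn: ramps sit inside the stated window
    dawn = _ramp_profile(
        t_of_day,
        schedule.dawn_start,
        schedule.dawn_end - schedule.dawn_ramp,
        schedule.dawn_ramp,
        schedule.dawn_ramp,
    )
    mult = 1.0 + schedule.dawn_drop * dawn
    if day_index % 7 in schedule.exercise_days:
        ex = _ramp_profile(
            t_of_day,
            schedule.exercise_start,
            schedule.exercise_end,
            schedule.exercise_ramp_up,
            schedule.exercise_ramp_down,
        )
        mult *= 1.0 + schedule.exercise_gain * ex
    return mult


@dataclass(frozen=True)
class MealEvent:
    """A meal: clock time (minutes of day), true and announced carbohydrate grams."""

    time: float
    true_cho: float
    announced_cho: float
    announcement_lead: float = 30.0  # min before intake

    def __post_init__(self) -> None:
        if self.true_cho <= 0 or self.announced_cho <= 0:
            raise ValueError("carbohydrate amounts must be positive")


def announce_meal(
    time: float,
    true_cho: float,
    uncertainty: float,
    rng: np.random.Generator,
    lead: float = 30.0,
) -> MealEvent:
    """Meal announcement with uniform +/- carb-counting error.

    announced = true * (1 + U(-u, +u)); the event is announced ``lead``
    minutes before intake.
    """
    if not (0 <= uncertainty < 1):
        raise ValueError("uncertainty must be in [0, 1)")
    factor = 1.0 + rng.uniform(-uncertainty, uncertainty)
    return MealEvent(time, true_cho, true_cho * factor, announcement_lead=lead)


def steady_state(patient: PatientParameters, basal_rate: float) -> np.ndarray:
    """Analytic fixed point of the ODEs under constant basal, no meals, nominal SI."""
    u = basal_rate / 60.0  # U/min
    isc = u * patient.sc_absorption_time
    x = patient.si_nominal * u
    g = patient.egp(x) / (patient.glucose_effectiveness + x / 100.0)
    g = max(g, GLUCOSE_FLOOR)
    return np.array([isc, isc, x, g, 0.0, 0.0])


def step(
    patient: PatientParameters,
    state: np.ndarray,
    basal: float,
    bolus: float,
    meal_cho: float,
    si_mult: float,
    dt: float = SIM_DT,
) -> tuple[np.ndarray, float]:
    """Advance the physiological state by ``dt`` minutes (Heun's method).

    ``bolus`` (U) and ``meal_cho`` (g; bioavailability scaling happens
    here) are impulses entering at the start of this step; ``basal`` is in
    U/h.  Returns (next_state, glucose).
    """
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must be in (0, 1] minutes for integration accuracy")
    s = np.array(state, dtype=float)
    s[0] += bolus
    s[4] += meal_cho * patient.meal_bioavailability
    k1 = _deriv(patient, s, basal / 60.0, si_mult)
    k2 = _deriv(patient, s + dt * k1, basal / 60.0, si_mult)
    nxt = s + 0.5 * dt * (k1 + k2)
    if not np.all(np.isfinite(nxt)):
        raise FloatingPointError("virtual patient state became non-finite")
    nxt[3] = max(nxt[3], GLUCOSE_FLOOR)
    return nxt, float(nxt[3])


def _deriv(
    patient: PatientParameters, s: np.ndarray, u: float, si_mult: float
) -> np.ndarray:
    """Right-hand side of the ODE system; ``u`` is insulin delivery in U/min."""
    isc1, isc2, x, g, q1, q2 = s
    tau_i = patient.sc_absorption_time
    tau_m = patient.meal_time_to_peak
    return np.array(
        [
            u - isc1 / tau_i,
            (isc1 - isc2) / tau_i,
            patient.insulin_action_rate
            * (patient.si_nominal * si_mult * isc2 / tau_i - x),
            -(patient.glucose_effectiveness + x / 100.0) * g
            + patient.egp(x)
            + (q2 / tau_m) * 1000.0 / patient.distribution_volume,
            -q1 / tau_m,
            (q1 - q2) / tau_m,
        ]
    )


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a reproducible synthetic cohort."""

    n_subjects: int
    rng_seed: int = 0
    basal_glucose: tuple = (110.0, 130.0)
    glucose_effectiveness: tuple = (0.004, 0.006)
    si_nominal: tuple = (30.0, 42.0)
    insulin_action_rate: tuple = (0.010, 0.015)
    sc_absorption_time: tuple = (8.0, 12.0)
    distribution_volume: tuple = (110.0, 160.0)
    meal_time_to_peak: tuple = (45.0, 65.0)
    meal_bioavailability: tuple = (0.7, 0.9)
    weight: tuple = (50.0, 90.0)
    equilibrium_basal: tuple = (0.8, 1.25)
    # deliberate open-loop mis-titration: standard regimen = factor x equilibrium
    mistitration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in (
            "basal_glucose",
            "glucose_effectiveness",
            "si_nominal",
            "insulin_action_rate",
            "sc_absorption_time",
            "distribution_volume",
            "meal_time_to_peak",
            "meal_bioavailability",
            "weight",
            "equilibrium_basal",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}")


_RANGE_FIELDS = (
    "basal_glucose",
    "glucose_effectiveness",
    "si_nominal",
    "insulin_action_rate",
    "sc_absorption_time",
    "distribution_volume",
    "meal_time_to_peak",
    "meal_bioavailability",
    "weight",
    "equilibrium_basal",
)


def generate_cohort(spec: CohortSpec) -> list[PatientParameters]:
    """Sample a reproducible cohort from the spec's parameter ranges."""
    rng = np.random.default_rng(spec.rng_seed)
    cohort = []
    for _ in range(spec.n_subjects):
        kw = {
            name: float(rng.uniform(*getattr(spec, name))) for name in _RANGE_FIELDS
        }
        p = PatientParameters(**kw)
        # rough bookkeeping: basal covers about half of total daily insulin
        tdi = 2.0 * 24.0 * p.equilibrium_basal
        cohort.append(replace(p, tdi_reference=tdi))
    return cohort


def standard_regimen(
    patient: PatientParameters, mistitration_factor: float = 1.0
) -> InsulinRegimen:
    """The subject's physician-optimised open-loop regimen.

    Equilibrium basal and the exactly meal-covering IC ratio; the basal
    rate is optionally scaled by a deliberate mis-titration factor for
    stress scenarios (a factor > 1 over-delivers basal insulin and pushes
    the subject hypoglycaemic).
    """
    return InsulinRegimen(
        basal_rate=patient.equilibrium_basal * mistitration_factor,
        ic_ratio=patient.equilibrium_ic_ratio(),
    )


@dataclass(frozen=True)
class DayResult:
    """One simulated day: CGM trace, pump record, end state and failure flag."""

    trace: GlucoseTrace
    pump: PumpRecord
    end_state: np.ndarray
    failed: bool


def run_day(
    patient: PatientParameters,
    regimen: InsulinRegimen,
    meals: list[MealEvent],
    schedule: SISchedule | None = None,
    *,
    day_index: int = 0,
    initial_state: np.ndarray | None = None,
    start_time: pd.Timestamp | None = None,
    bolus_at_announcement: bool = False,
    dt: float = SIM_DT,
) -> DayResult:
    """Simulate 24 h under a fixed regimen; emit a 5-min CGM trace + pump record.

    Boluses are computed from the announced carbohydrates via the current IC
    ratio and delivered at meal intake by default (at announcement time when
    ``bolus_at_announcement``).  The CGM grid samples the plasma glucose at
    t = 0, 5, ..., 1435 min.
    """
    schedule = schedule if schedule is not None else SISchedule(enabled=False)
    state = (
        np.array(initial_state, dtype=float)
        if initial_state is not None
        else steady_state(patient, regimen.basal_rate)
    )
    n_steps = int(round(MINUTES_PER_DAY / dt))
    stride = int(round(CGM_INTERVAL / dt))
    bolus_plan: dict[int, float] = {}
    meal_plan: dict[int, float] = {}
    bolus_events = []
    for m in meals:
        units = bolus_from_meal(regimen.ic_ratio, m.announced_cho)
        t_bolus = m.time - m.announcement_lead if bolus_at_announcement else m.time
        t_bolus = max(t_bolus, 0.0)
        bi = int(round(t_bolus / dt))
        bolus_plan[bi] = bolus_plan.get(bi, 0.0) + units
        bolus_events.append((t_bolus, units))
        meal_plan[int(round(m.time / dt))] = (
            meal_plan.get(int(round(m.time / dt)), 0.0) + m.true_cho
        )
    cgm = np.empty(n_steps // stride)
    failed = False
    for i in range(n_steps):
        if i % stride == 0:
            cgm[i // stride] = state[3]
        mult = si_multiplier(schedule, (i * dt) % MINUTES_PER_DAY, day_index)
        state, g = step(
            patient,
            state,
            regimen.basal_rate,
            bolus_plan.get(i, 0.0),
            meal_plan.get(i, 0.0),
            mult,
            dt,
        )
        if g <= GLUCOSE_FLOOR:
            failed = True
    t0 = (
        start_time
        if start_time is not None
        else pd.Timestamp("2000-01-01 00:00") + pd.Timedelta(days=day_index)
    )
    trace = GlucoseTrace(cgm, start_time=t0, sampling_interval=CGM_INTERVAL)
    pump = PumpRecord(
        basal_series=np.full(len(trace), regimen.basal_rate),
        bolus_events=tuple(bolus_events),
        sampling_interval=CGM_INTERVAL,
        start_time=t0,
    )
    return DayResult(trace=trace, pump=pump, end_state=state, failed=failed)


def mixed_cohort_spec(n_subjects: int, rng_seed: int = 0) -> CohortSpec:
    """Cohort spec emulating a mixed-age population (children through adults).

    Compared with the default (adult-like) ranges this widens insulin
    sensitivity, glucose distribution volume (children ~45 dl at 30 kg),
    body weight and basal insulin needs, giving the between-subject
    heterogeneity of an age-diverse study population.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        rng_seed=rng_seed,
        si_nominal=(18.0, 60.0),
        distribution_volume=(45.0, 180.0),
        equilibrium_basal=(0.3, 2.0),
        glucose_effectiveness=(0.004, 0.007),
        basal_glucose=(100.0, 140.0),
        insulin_action_rate=(0.008, 0.016),
        weight=(30.0, 100.0),
    )


def simulate_open_loop(
    patient: PatientParameters,
    regimen: InsulinRegimen,
    meal_protocol,
    n_days: int,
    uncertainty: float,
    rng: np.random.Generator,
    schedule: SISchedule | None = None,
    *,
    initial_state: np.ndarray | None = None,
) -> tuple[GlucoseTrace, PumpRecord, bool]:
    """Simulate ``n_days`` under a fixed regimen; concatenated trace + pump.

    ``meal_protocol`` is a sequence of (clock-minute, grams) pairs applied
    every day with fresh announcement errors.  Returns the multi-day CGM
    trace, the matching pump record and the failure flag.
    """
    state = (
        np.array(initial_state, dtype=float)
        if initial_state is not None
        else steady_state(patient, patient.equilibrium_basal)
    )
    traces, basals, events = [], [], []
    failed = False
    for d in range(n_days):
        meals = [
            announce_meal(t, cho, uncertainty, rng) for t, cho in meal_protocol
        ]
        res = run_day(
            patient, regimen, meals, schedule, day_index=d, initial_state=state
        )
        state = res.end_state
        failed |= res.failed
        traces.append(res.trace)
        basals.append(res.pump.basal_series)
        events.extend(
            (d * MINUTES_PER_DAY + t, u) for t, u in res.pump.bolus_events
        )
    trace = GlucoseTrace(
        np.concatenate([t.values for t in traces]),
        start_time=traces[0].start_time,
        sampling_interval=CGM_INTERVAL,
    )
    pump = PumpRecord(
        np.concatenate(basals),
        bolus_events=tuple(events),
        sampling_interval=CGM_INTERVAL,
        start_time=trace.start_time,
    )
    return trace, pump, failed


def save_cohort(path, spec: CohortSpec, cohort: list[PatientParameters]) -> None:
    """Write the cohort spec and sampled parameters to JSON."""
    payload = {
        "spec": asdict(spec),
        "subjects": [asdict(p) for p in cohort],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_cohort(path) -> tuple[CohortSpec, list[PatientParameters]]:
    with open(path) as fh:
        payload = json.load(fh)
    raw = payload["spec"]
    raw = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    spec = CohortSpec(**raw)
    cohort = [PatientParameters(**s) for s in payload["subjects"]]
    return spec, cohort
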