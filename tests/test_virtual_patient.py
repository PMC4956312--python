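"""Minimal-model environment: dynamics, schedules, meals, cohorts."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apctl import (
    CohortSpec,
    InsulinRegimen,
    MealEvent,
    PatientParameters,
    SISchedule,
    announce_meal,
    generate_cohort,
    mixed_cohort_spec,
    run_day,
    si_multiplier,
    standard_regimen,
    step,
    time_in_ranges,
)
from apctl.virtual_patient import GLUCOSE_FLOOR, steady_state
from conftest import MEAL_PROTOCOL


class TestSIMultiplier:
    def test_disabled_schedule_is_identity(self):
        sched = SISchedule(enabled=False)
        assert all(
            si_multiplier(sched, t, d) == 1.0
            for t in (0, 360, 1140)
            for d in range(7)
        )

    def test_dawn_plateau_drops_25_percent(self):
        assert si_multiplier(SISchedule(), 6 * 60.0, 1) == pytest.approx(0.75)

    def test_exercise_plateau_raises_33_percent(self):
        # day index 0 is an exercise day; 19:00 sits on the plateau
        assert si_multiplier(SISchedule(), 19 * 60.0, 0) == pytest.approx(1.33)

    def test_no_exercise_on_rest_days(self):
        assert si_multiplier(SISchedule(), 19 * 60.0, 1) == pytest.approx(1.0)

    def test_multiplier_trace_is_continuous(self):
        sched = SISchedule()
        dt = 1.0
        # steepest allowed slope: exercise gain over its 30-min ramp
        max_step = (0.33 / 30.0 + 0.25 / 30.0) * dt + 1e-9
        for day in (0, 1):
            ts = np.arange(0, 1440, dt)
            vals = np.array([si_multiplier(sched, t, day) for t in ts])
            assert np.max(np.abs(np.diff(vals))) <= max_step


class TestDynamics:
    def test_equilibrium_holds_for_a_day(self, default_patient):
        p = default_patient
        reg = standard_regimen(p)
        res = run_day(p, reg, meals=[], initial_state=steady_state(p, reg.basal_rate))
        assert np.ptp(res.trace.values) < 1.0
        assert abs(res.trace.values[-1] - p.basal_glucose) < 1.0

    def test_meal_without_bolus_raises_glucose(self, default_patient):
        p = default_patient
        reg = replace(standard_regimen(p), ic_ratio=0.01)  # negligible bolus
        meal = MealEvent(300.0, 60.0, 60.0)
        res = run_day(
            p, reg, [meal], initial_state=steady_state(p, reg.basal_rate)
        )
        pre = res.trace.values[int(300 / 5) - 1]
        within_hour = res.trace.values[int(300 / 5) : int(360 / 5)]
        assert within_hour.max() > pre + 5.0

    def test_integration_step_halving_changes_little(self, default_patient):
        p = default_patient
        reg = standard_regimen(p)
        meals = [MealEvent(t, c, c) for t, c in MEAL_PROTOCOL]
        state0 = steady_state(p, reg.basal_rate)
        res1 = run_day(p, reg, meals, initial_state=state0, dt=1.0)
        res05 = run_day(p, reg, meals, initial_state=state0, dt=0.5)
        assert np.max(np.abs(res1.trace.values - res05.trace.values)) < 0.5

    def test_step_rejects_coarse_dt(self, default_patient):
        with pytest.raises(ValueError):
            step(default_patient, np.zeros(6) + 1.0, 1.0, 0.0, 0.0, 1.0, dt=5.0)

    def test_meal_mass_conservation(self, default_patient):
        """Integrated appearance equals bioavailable carbohydrate within 1%."""
        p = default_patient
        state = steady_state(p, p.equilibrium_basal)
        dt = 1.0
        total = 0.0
        cho = 60.0
        for i in range(3000):  # 50 h, long past the gut transit
            bolus = 0.0
            meal = cho if i == 10 else 0.0
            ra_g_per_min = state[5] / p.meal_time_to_peak
            total += ra_g_per_min * dt
            state, _ = step(p, state, p.equilibrium_basal, bolus, meal, 1.0, dt)
        assert total == pytest.approx(cho * p.meal_bioavailability, rel=0.01)

    def test_monotone_dose_response(self, default_patient):
        p = default_patient
        rng_seed = 17
        means = []
        for factor in (1.0, 1.1):
            reg = InsulinRegimen(p.equilibrium_basal * factor, p.equilibrium_ic_ratio())
            rng = np.random.default_rng(rng_seed)
            meals = [
                announce_meal(t, c, 0.5, rng) for t, c in MEAL_PROTOCOL
            ]
            res = run_day(p, reg, meals, initial_state=steady_state(p, reg.basal_rate))
            means.append(res.trace.values.mean())
        assert means[1] <= means[0]

    def test_excessive_basal_causes_hypoglycaemia(self, default_patient):
        p = default_patient
        reg = InsulinRegimen(p.equilibrium_basal * 1.5, p.equilibrium_ic_ratio())
        rng = np.random.default_rng(3)
        meals = [announce_meal(t, c, 0.0, rng) for t, c in MEAL_PROTOCOL]
        res = run_day(p, reg, meals, initial_state=steady_state(p, reg.basal_rate))
        ranges = time_in_ranges(res.trace)
        assert ranges[1] + ranges[2] > 0.0

    def test_floor_flags_failure(self, default_patient):
        p = default_patient
        reg = InsulinRegimen(p.equilibrium_basal * 4.0, p.equilibrium_ic_ratio())
        res = run_day(p, reg, [], initial_state=steady_state(p, reg.basal_rate))
        assert res.failed
        assert res.trace.values.min() >= GLUCOSE_FLOOR

    def test_trace_and_pump_share_grid(self, default_patient):
        p = default_patient
        reg = standard_regimen(p)
        meals = [MealEvent(t, c, c) for t, c in MEAL_PROTOCOL]
        res = run_day(p, reg, meals, initial_state=steady_state(p, reg.basal_rate))
        assert len(res.trace) == len(res.pump.basal_series) == 288


class TestMealAnnouncement:
    def test_zero_uncertainty_is_exact(self):
        m = announce_meal(420.0, 50.0, 0.0, np.random.default_rng(0))
        assert m.announced_cho == pytest.approx(50.0)
        assert m.announcement_lead == 30.0

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_announcement_within_stated_band(self, seed):
        rng = np.random.default_rng(seed)
        m = announce_meal(420.0, 60.0, 0.5, rng)
        assert 0.5 * 60 <= m.announced_cho <= 1.5 * 60

    def test_announcement_unbiased(self):
        rng = np.random.default_rng(1)
        ratios = [
            announce_meal(0.0, 50.0, 0.5, rng).announced_cho / 50.0
            for _ in range(10_000)
        ]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)

    def test_invalid_uncertainty(self):
        with pytest.raises(ValueError):
            announce_meal(0.0, 50.0, 1.0, np.random.default_rng(0))


class TestCohort:
    def test_same_seed_reproduces(self):
        spec = CohortSpec(n_subjects=5, rng_seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert a == b

    def test_empty_cohort(self):
        assert generate_cohort(CohortSpec(n_subjects=0)) == []

    def test_sampled_parameters_within_ranges(self):
        spec = mixed_cohort_spec(1000, rng_seed=3)
        for p in generate_cohort(spec):
            for name in (
                "si_nominal",
                "glucose_effectiveness",
                "distribution_volume",
                "equilibrium_basal",
                "basal_glucose",
            ):
                lo, hi = getattr(spec, name)
                assert lo <= getattr(p, name) <= hi

    def test_standard_regimen_titration(self, default_patient):
        reg = standard_regimen(default_patient)
        assert reg.basal_rate == default_patient.equilibrium_basal
        stressed = standard_regimen(default_patient, 1.4)
        assert stressed.basal_rate == pytest.approx(1.4 * reg.basal_rate)
        assert stressed.ic_ratio == reg.ic_ratio  # stress applies to basal only

    def test_cohort_json_round_trip(self, tmp_path):
        from apctl import load_cohort, save_cohort

        spec = CohortSpec(n_subjects=3, rng_seed=1)
        cohort = generate_cohort(spec)
        path = tmp_path / "cohort.json"
        save_cohort(path, spec, cohort)
        spec2, cohort2 = load_cohort(path)
        assert spec2 == spec
        assert cohort2 == cohort
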