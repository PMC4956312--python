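import numpy as np
import pytest

import apctl


MEAL_PROTOCOL = [(7 * 60.0, 50.0), (13 * 60.0, 70.0), (19 * 60.0, 60.0)]


@pytest.fixture(scope="session")
def default_patient() -> apctl.PatientParameters:
    return apctl.PatientParameters()


@pytest.fixture(scope="session")
def small_cohort() -> list:
    return apctl.generate_cohort(apctl.CohortSpec(n_subjects=4, rng_seed=7))


def make_trace(values, interval=5.0) -> apctl.GlucoseTrace:
    return apctl.GlucoseTrace(np.asarray(values, float), sampling_interval=interval)


def constant_day(value: float, interval: float = 5.0) -> apctl.GlucoseTrace:
    n = int(1440 / interval)
    return make_trace(np.full(n, value), interval)
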