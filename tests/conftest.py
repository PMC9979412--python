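import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sleeplife as sl

logging.getLogger("sleeplife").setLevel(logging.ERROR)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def zero_sleep_effects():
    return {k: {"healthy": 0.0, "intermediate": 0.0, "poor": 0.0} for k in (1, 2, 3)}


@pytest.fixture
def constant_truth():
    """Constant hazards (b=0), no covariate or sleep effects: exponential."""
    return sl.SimulationTruth(
        baseline={
            1: sl.GompertzIntensity(0.03, 0.0),
            2: sl.GompertzIntensity(0.02, 0.0),
            3: sl.GompertzIntensity(0.05, 0.0),
        },
        sleep_log_hr=zero_sleep_effects(),
        covariate_log_hr={},
        missing_rates={},
        prevalent_cvd_rate=0.0,
        seed=101,
    )


@pytest.fixture
def small_cohort():
    """2,000 participants from the default truth, fixed seed."""
    truth = sl.SimulationTruth(seed=7)
    participants, events = sl.generate_cohort(truth, 2000)
    return truth, participants, events


@pytest.fixture
def toy_participants():
    """Hand-built participant table exercising every exclusion stage."""
    base = {
        "chronotype": "definitely_morning",
        "sleep_duration": 8.0,
        "insomnia": "never_rarely",
        "snoring": "no",
        "sleepiness": "never_rarely",
        "screen_time": 3.0,
        "smoking": "never",
        "mental_health": "no",
    }
    rows = [
        # kept: clean, no events
        dict(person_id=0, sex="female", enroll_age=50.0, prevalent_cvd=False,
             cvd_age=np.nan, death_age=np.nan, censor_age=62.0, **base),
        # stage 1: missing snoring
        dict(person_id=1, sex="female", enroll_age=52.0, prevalent_cvd=False,
             cvd_age=np.nan, death_age=np.nan, censor_age=63.0, **{**base, "snoring": None}),
        # stage 2: prevalent CVD (also has missing covariate, but removed earlier)
        dict(person_id=2, sex="male", enroll_age=55.0, prevalent_cvd=True,
             cvd_age=np.nan, death_age=np.nan, censor_age=65.0, **{**base, "smoking": None}),
        # stage 3: missing smoking covariate
        dict(person_id=3, sex="male", enroll_age=47.0, prevalent_cvd=False,
             cvd_age=np.nan, death_age=np.nan, censor_age=60.0, **{**base, "smoking": None}),
        # stage 4: CVD 1.9 years after enrollment
        dict(person_id=4, sex="female", enroll_age=49.0, prevalent_cvd=False,
             cvd_age=50.9, death_age=np.nan, censor_age=61.0, **base),
        # kept: CVD 2.1 years after enrollment, then death
        dict(person_id=5, sex="male", enroll_age=56.0, prevalent_cvd=False,
             cvd_age=60.0, death_age=70.0, censor_age=82.0, **base),
        # kept: death beyond tau -> censored at 81
        dict(person_id=6, sex="male", enroll_age=56.0, prevalent_cvd=False,
             cvd_age=np.nan, death_age=83.0, censor_age=85.0, **base),
        # kept: healthy-censored at 68.3
        dict(person_id=7, sex="female", enroll_age=56.0, prevalent_cvd=False,
             cvd_age=np.nan, death_age=np.nan, censor_age=68.3, **base),
    ]
    return pd.DataFrame(rows)
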