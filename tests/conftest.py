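import datetime
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from stepcomply import PatientMeta, SimConfig, StepDay, simulate_cohort


@pytest.fixture
def meta():
    return PatientMeta(
        patient_id="P01",
        surgery_date=datetime.date(2016, 5, 10),
        age=64.0,
        gender="female",
        bmi=29.5,
        asa=2,
        device="wrist",
    )


@pytest.fixture
def clip_meta():
    return PatientMeta(
        patient_id="P02",
        surgery_date=datetime.date(2016, 6, 1),
        age=58.0,
        gender="male",
        bmi=31.0,
        asa=2,
        device="clip",
    )


def make_day(day_index=0, **hour_steps):
    """StepDay with counts given as h<hour>=<steps> keyword arguments."""
    hourly = np.zeros(24, dtype=np.int64)
    for key, steps in hour_steps.items():
        hourly[int(key.lstrip("h"))] = steps
    return StepDay(day_index=day_index, hourly=hourly)


@pytest.fixture
def day_factory():
    return make_day


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=8, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a clip-specific postoperative data-quality degradation."""
    cfg = SimConfig(
        n_patients=24,
        seed=7,
        clip_postop_window_shrink=4,
        clip_postop_intensity=0.15,
        clip_forget_prob=0.12,
    )
    return simulate_cohort(cfg)
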