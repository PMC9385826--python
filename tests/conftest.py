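import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from threescenarios.cohort import PatientRecord, RatioSample

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def hand_censored_sample():
    """Four patients, one censored: the hand-computable KM fixture."""
    return RatioSample(ratios=[0.5, 1.0, 1.5, 2.0], events=[1, 0, 1, 1])


def make_record(pid="P1", est=12.0, ost=9.0, event="died", **kwargs):
    base = dict(
        patient_id=pid, age_years=67, sex="male", cancer_type="pancreatic",
        ecog=1, education="highschool_or_above",
        time_from_diagnosis="gt_8_weeks",
        consultation_number="third_or_later",
        est_months=est, ost_months=ost, event=event,
    )
    base.update(kwargs)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
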