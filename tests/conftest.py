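import dataclasses

import numpy as np
import pytest

from cervitex.cohort import ABNORMAL, PatientRecord, load_cohort


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture(scope="session")
def cohort_df(cohort):
    from cervitex.cohort import cohort_frame
    return cohort_frame(cohort)


def make_record(**overrides) -> PatientRecord:
    """A single in-range patient record with overridable fields."""
    base = dict(
        patient_id=1, gender="female", age=30, h_mean=4.0, angle_1=80.0,
        angle_2=55.0, area=1000.0, contrast=0.5, homogeneity=0.9,
        correlation=0.8, energy=0.4, input_class=ABNORMAL, gep_h=0.1,
        predicted_class=ABNORMAL,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
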