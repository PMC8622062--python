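import numpy as np
import pytest
from hypothesis import strategies as st

from hopescore import Mechanism, PatientRecord, Sex


@pytest.fixture
def rng():
    return np.random.default_rng(20211112)


def make_record(
    age=33.0,
    sex=Sex.FEMALE,
    mechanism=Mechanism.EXPOSURE,
    temperature=22.7,
    potassium=4.2,
    cpr_duration=95.0,
    **kwargs,
):
    """A valid record with the cohort's median covariates, overridable."""
    return PatientRecord(
        id=kwargs.pop("id", "test"),
        age=age,
        sex=sex,
        mechanism=mechanism,
        temperature=temperature,
        potassium=potassium,
        cpr_duration=cpr_duration,
        **kwargs,
    )


@pytest.fixture
def median_record():
    return make_record()


#: Hypothesis strategy over physiologically spanning (incl. out-of-range) records.
record_strategy = st.builds(
    make_record,
    age=st.floats(0.0, 100.0),
    sex=st.sampled_from(list(Sex)),
    mechanism=st.sampled_from(list(Mechanism)),
    temperature=st.floats(10.0, 35.0),
    potassium=st.floats(0.5, 20.0, exclude_min=True),
    cpr_duration=st.floats(5.0, 400.0, exclude_min=True),
)


def random_records(rng, n):
    """Plain-numpy batch of valid random records (for larger sweeps)."""
    return [
        make_record(
            id=f"r{i}",
            age=float(rng.uniform(0, 95)),
            sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            mechanism=list(Mechanism)[rng.integers(len(Mechanism))],
            temperature=float(rng.uniform(12, 33)),
            potassium=float(rng.uniform(1.5, 17)),
            cpr_duration=float(rng.uniform(10, 350)),
        )
        for i in range(n)
    ]
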