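import numpy as np
import pytest

from aphasia_econ.fixtures import synthetic_study_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic 20-patient reconstruction of the study cohort."""
    return synthetic_study_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20210917)
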