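import numpy as np
import pytest

from nirsmse import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast-to-generate cohort: short sessions, 4 participants."""
    return CohortSpec(
        n_participants=6,
        rest_duration_s=12.0,
        task_duration_s=30.0,
        seed=7,
    )
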