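import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from levospeech.synthgen import SyntheticCohortSpec, gen_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("levospeech").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (51 PD / 43 HC), shared across tests."""
    return gen_cohort(SyntheticCohortSpec(seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with the dopaminergic response switched off."""
    return gen_cohort(SyntheticCohortSpec(seed=0, effect_scale=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
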