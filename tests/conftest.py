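import numpy as np
import pytest

from cptddm import DDMParameters, generate_trial_sequence


#: Group-mean very-preterm diffusion parameters used across tests.
VP_PARAMS = DDMParameters(v=0.211, a=0.112, ter=0.253)


@pytest.fixture(scope="session")
def vp_params() -> DDMParameters:
    return VP_PARAMS


@pytest.fixture(scope="session")
def template_session():
    """One task template shared by tests that only need structure."""
    return generate_trial_sequence(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
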