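import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_phantom_spec():
    """Phantom parameterized by the measured sheep averages."""
    from septumkit.synthetic_data import PhantomSpec

    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantom(table1_phantom_spec):
    from septumkit.synthetic_data import make_septal_tensor_phantom

    return make_septal_tensor_phantom(table1_phantom_spec)


@pytest.fixture(scope="session")
def gtab6():
    from septumkit.dti import icosahedral_6

    return icosahedral_6()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
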