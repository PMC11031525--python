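import numpy as np
import pytest

from coroseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def normal_phantom():
    """One deterministic two-trunk phantom with wide ostium separation."""
    return generate_phantom(PhantomSpec(variant="normal", noise_seed=11))


@pytest.fixture(scope="session")
def shared_phantom():
    return generate_phantom(PhantomSpec(variant="anomalous_shared", noise_seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
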