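import numpy as np
import pytest

from bristlewing.kinematics import FluidProperties
from bristlewing.synthetic import MorphFixtureSpec, ProtocolSpec, make_morphology, make_protocol


@pytest.fixture(scope="session")
def morph():
    """Default bristled-wing fixture (session-wide: quadrature is not free)."""
    return make_morphology(MorphFixtureSpec(seed=0))


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def proto(morph):
    """Default noisy protocol, seed 1."""
    return make_protocol(ProtocolSpec(seed=1), planform=morph.planform)


@pytest.fixture(scope="session")
def proto_clean(morph):
    """Noise-free default protocol."""
    return make_protocol(ProtocolSpec(seed=1, noise_sigma_deg=0.0),
                         planform=morph.planform)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
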