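import numpy as np
import pytest

from optogate import HillParams, KineticParams


@pytest.fixture
def v1_hill() -> HillParams:
    """Transfer-function parameter set of the characterized v1.0 system."""
    return HillParams(y0=2000.0, dy=106700.0, n=1.88, K=4.66)


@pytest.fixture
def default_kinetics() -> KineticParams:
    """Plausible cascade rates on the tens-of-minutes response timescale."""
    return KineticParams(kp=0.02, kg=0.05, kd=0.03, tau=15.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
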