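import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_biofilm_params():
    """Desk-scale biofilm constants for structural tests."""
    from groupsel.biofilm import BiofilmParams

    return BiofilmParams(K_BF=60, relax_steps=50, steady_steps=300)
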