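import numpy as np
import pytest

from hepaquant import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A mid-fibrosis phantom with no noise; shared across read-only tests."""
    return generate_phantom(
        PhantomSpec(side_px=241, fibrosis_fraction=0.15, lumen_fraction=0.08,
                    noise_sd=0.0, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
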