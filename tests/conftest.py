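import numpy as np
import pytest

from codae.synth import SynthConfig, generate_xyrcs, fixture_bank


@pytest.fixture(scope="session")
def fixtures():
    return fixture_bank()


@pytest.fixture(scope="session")
def xyrcs_small():
    """A small XYRCS batch shared by fast tests."""
    return generate_xyrcs(SynthConfig(n=64, image_size=32, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
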