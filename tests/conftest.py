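import numpy as np
import pytest

from phosphodecode import core, synth


@pytest.fixture(scope="session")
def panel():
    return core.default_panel()


@pytest.fixture(scope="session")
def combinatorial_panel():
    return core.combinatorial_panel(3)


@pytest.fixture
def two_site_truth():
    # dominant T340 + S343 additive model, used across round-trip tests
    return synth.ArrayGroundTruth(
        theta=(0.0, 0.0, 0.0, 0.0, 5.0, 0.0, 3.0), intercept=2.0, noise_sd=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
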