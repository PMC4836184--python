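import numpy as np
import pytest

import framebias as fb


@pytest.fixture(scope="session")
def bundle():
    return fb.fixture_bundle()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def calibration_population():
    """Mid-size zero-gradient 2013-like population shared across tests."""
    config = fb.scenario_for_year(2013, population_size=60_000, seed=4242,
                                  with_gradients=False)
    return fb.generate_population(config)
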