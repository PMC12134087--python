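import numpy as np
import pytest

from revisit.synthetic import StudyConfig, gen_study


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared across tests."""
    cfg = StudyConfig(n_bulls=2, n_cows=2, duration_days=150, seed=1234)
    return gen_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_101)
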