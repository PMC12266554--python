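import numpy as np
import pytest
from hypothesis import settings

import nutrail as nt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def diets():
    return nt.PAPER_DIETS


@pytest.fixture(scope="session")
def target():
    """The study's intake target: (30, 20) mg/bee on the P30:L20 rail."""
    return nt.IntakeTarget(point=nt.NutrientPoint(30.0, 20.0))


@pytest.fixture(scope="session")
def default_experiment():
    """One full default-design simulated experiment, shared across tests."""
    return nt.simulate_experiment(seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
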