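import numpy as np
import pytest

from smcnet.network import parse_network
from smcnet.smc import load_smc_model, run_conditions

SMALL_NET = """
species Input role=input
species A
species B
species C role=output
=> Input w=0.5
Input => A
A & !B => C
A => B w=0.85
"""


@pytest.fixture()
def small_model():
    return parse_network(SMALL_NET)


@pytest.fixture(scope="session")
def smc_model():
    return load_smc_model()


@pytest.fixture(scope="session")
def condition_states(smc_model):
    """Steady states of the three condition experiments (shared: expensive)."""
    return run_conditions(smc_model, ("Baseline", "KO", "Rapa"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211213)
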