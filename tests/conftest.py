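import numpy as np
import pytest

from castsim import ARMS, ArmPrior, OutcomeData, builtin_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture
def prior():
    return ArmPrior()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_data(rng, means, ns, sd=20.0):
    """Outcome data with given per-arm true means and sizes."""
    return OutcomeData(
        {a: rng.normal(m, sd, n) for a, m, n in zip(ARMS, means, ns)}
    )
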