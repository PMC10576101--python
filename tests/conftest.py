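import numpy as np
import pytest
from hypothesis import settings

import panicseir as ps

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def baseline() -> ps.Scenario:
    return ps.load_scenario("baseline")


@pytest.fixture(scope="session")
def pm(baseline) -> ps.PayoffMatrix:
    return baseline.payoffs


@pytest.fixture(scope="session")
def epi(baseline) -> ps.EpiParams:
    return baseline.epi


def draw_payoffs(rng: np.random.Generator) -> ps.PayoffMatrix:
    """A random payoff matrix satisfying the ordering assumptions."""
    b6 = rng.uniform(0.5, 3.0)
    b5 = b6 + rng.uniform(0.1, 3.0)
    b4 = b5 + rng.uniform(0.1, 3.0)
    b3 = b4 + rng.uniform(0.1, 3.0)
    b2 = rng.uniform(1.0, 10.0)
    b1 = b2 + rng.uniform(0.1, 8.0)
    return ps.PayoffMatrix(
        b1=b1, b2=b2, b3=b3, b4=b4, b5=b5, b6=b6,
        c1=rng.uniform(0.5, 8.0),
        c11=rng.uniform(0.5, 8.0),
        c21=rng.uniform(0.5, 8.0),
    )


def draw_rates(rng: np.random.Generator) -> ps.GameRates:
    return ps.GameRates(
        lambda1=rng.uniform(0.2, 2.0),
        rho1=rng.uniform(0.2, 2.0),
        p21=rng.uniform(0.0, 2.0),
        q21=rng.uniform(0.0, 2.0),
    )
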