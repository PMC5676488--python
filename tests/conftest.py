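import numpy as np
import pytest

from tumordyn import ModelParams, positive_equilibria
from tumordyn.scenarios import kuznetsov_fixture


@pytest.fixture(scope="session")
def kuz_params() -> ModelParams:
    return kuznetsov_fixture().params


@pytest.fixture(scope="session")
def kuz_equilibria(kuz_params):
    """The three positive equilibria of the flagship parameter set, sorted by y*."""
    eqs = positive_equilibria(kuz_params)
    assert len(eqs) == 3
    return eqs


@pytest.fixture(scope="session")
def global_stable_params() -> ModelParams:
    """Parameters in the global-elimination regime: sigma > f*delta, delta*beta > mu > alpha."""
    return ModelParams(sigma=0.5, alpha=0.1, mu=0.2, delta=1.0, f=0.3, beta=0.5)


def random_params(rng, n: int):
    """Log-uniform positive parameter sets spanning the fixture's magnitude range."""
    for _ in range(n):
        vals = 10.0 ** rng.uniform(-3.0, 1.0, 6)
        yield ModelParams(*map(float, vals))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170)
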