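import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import labferm as lf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bulgaricus():
    return lf.get_preset("bulgaricus")


@pytest.fixture(scope="session")
def casei():
    return lf.get_preset("casei")


@pytest.fixture(scope="session")
def plantarum():
    return lf.get_preset("plantarum")


@pytest.fixture(scope="session")
def bulgaricus_traj(bulgaricus):
    """One full growth curve of the bulgaricus preset at S0 = 26 g/dm3."""
    init = lf.InitialConditions(S0=26.0, Q0=bulgaricus.Q0, X0=bulgaricus.X0, A0=0.0)
    return lf.simulate_to_stationarity(bulgaricus.params, init)


def random_valid_parameters(rng: np.random.Generator) -> lf.ModelParameters:
    """A physically plausible random parameter draw for property tests."""
    return lf.ModelParameters(
        mu_max=rng.uniform(0.1, 1.0),
        K_S=rng.uniform(1.0, 20.0),
        K_I=rng.uniform(10.0, 100.0),
        alpha=rng.uniform(0.0, 15.0),
        beta=rng.uniform(0.0, 1.0),
        gamma_XS=rng.uniform(0.05, 1.0),
        gamma_AS=rng.uniform(0.3, 1.5),
    )


def random_valid_init(rng: np.random.Generator) -> lf.InitialConditions:
    return lf.InitialConditions(
        S0=rng.uniform(5.0, 60.0),
        Q0=rng.uniform(0.1, 2.0),
        X0=rng.uniform(0.01, 0.5),
        A0=rng.uniform(0.0, 2.0),
    )
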