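import numpy as np
import pytest

from bayesbmc import load_fluoride_table
from bayesbmc.inference import McmcConfig
from bayesbmc.models import MODEL_NAMES, ParameterVector, make_spec


@pytest.fixture(scope="session")
def table3():
    """The bundled fluoride zebrafish summary table (assumed n = 6)."""
    return load_fluoride_table()


@pytest.fixture(scope="session")
def cm1(table3):
    return table3["cm_1dpf"]


@pytest.fixture()
def fast_mcmc():
    """Small but valid MCMC config for unit tests."""
    return McmcConfig(iterations=2_000, seed=65_323)


_THETA_RANGES = {
    "a": (2.0, 30.0),
    "g": (1.0, 5.0),
}


def random_theta(name: str, rng: np.random.Generator) -> ParameterVector:
    """A random parameter point inside the default prior support."""
    p = {"a": rng.uniform(*_THETA_RANGES["a"])}
    if name in ("exp2", "exp3"):
        p["b"] = rng.uniform(0.1, 2.5)
    elif name in ("exp4", "exp5"):
        p["b"] = rng.uniform(0.5, 20.0)
        p["c"] = rng.uniform(1.5, 15.0)
    elif name == "hill":
        p["b"] = rng.uniform(20.0, 150.0)
        p["c"] = rng.uniform(0.05, 5.0)
    elif name == "michaelis_menten":
        p["b"] = rng.uniform(20.0, 300.0)
        p["c"] = rng.uniform(0.05, 5.0)
    else:  # power, linear
        p["b"] = rng.uniform(10.0, 300.0)
    if name in ("exp3", "exp5", "hill", "power"):
        p["g"] = rng.uniform(*_THETA_RANGES["g"])
    return ParameterVector(p, sigma=rng.uniform(0.1, 0.5))


@pytest.fixture(scope="session")
def theta_sampler():
    return random_theta


@pytest.fixture(params=MODEL_NAMES)
def model_name(request):
    return request.param


@pytest.fixture()
def spec300(model_name):
    return make_spec(model_name, 300.0)
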