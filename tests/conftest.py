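import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crawlby.model import ParamSet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: parameter values shared by all of the study's figures (gamma_p varies)
BASE = dict(delta_p=0.9, delta_n=0.8, gamma_p=1.0, gamma_n=1.0, sigma=2.67, R=2.0)


@pytest.fixture
def base_params() -> ParamSet:
    """Below the bifurcation (gamma_p = 1 < gamma_p* ~ 2.414): consumer dies out."""
    return ParamSet(**BASE)


@pytest.fixture
def cycling_params() -> ParamSet:
    """Above the bifurcation (gamma_p = 3): no stable fixed point, cycles."""
    return ParamSet(**{**BASE, "gamma_p": 3.0})


def draw_valid_params(rng: np.random.Generator) -> ParamSet:
    """A random self-replenishing parameter set with group defense."""
    delta_p = rng.uniform(0.05, 0.95)
    delta_n = rng.uniform(0.05, 0.95)
    return ParamSet(
        delta_p=delta_p,
        delta_n=delta_n,
        gamma_p=10.0 ** rng.uniform(-1, 1),
        gamma_n=10.0 ** rng.uniform(-1, 1),
        sigma=10.0 ** rng.uniform(-1, 1),
        R=(1.0 - delta_n) + 10.0 ** rng.uniform(-2, 1),
    )


@pytest.fixture
def param_sampler():
    return draw_valid_params
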