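"""Shared fixtures: small synthetic datasets and reference parameter sets."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from dynising.params import NaturalParams, theta_dim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_weak_theta(seed: int, n: int, field_loc: float = -2.5,
                      field_sd: float = 0.5, coupling_max: float = 0.2) -> NaturalParams:
    """Random model in the weak-coupling regime the approximations assume."""
    r = np.random.default_rng(seed)
    d = theta_dim(n)
    theta = np.concatenate([
        r.normal(field_loc, field_sd, n),
        r.uniform(-coupling_max, coupling_max, d - n),
    ])
    return NaturalParams(theta, n)


@pytest.fixture(scope="session")
def log5_model():
    """Two neurons, theta = (0, 0, log 2): psi = log 5, eta = (0.6, 0.6, 0.4)."""
    return NaturalParams(np.array([0.0, 0.0, np.log(2.0)]), 2)
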