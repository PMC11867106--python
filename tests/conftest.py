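"""Shared fixtures and generators for the test suite.

All stochastic tests are seeded; hypothesis runs derandomized so the
suite is reproducible in any environment.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bdphylo import models as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_constant_params(rng: np.random.Generator) -> tuple[float, float, float, float]:
    """(lam, mu, rho, t) draws covering sub-, super- and near-critical cases."""
    lam = rng.uniform(0.05, 2.0)
    mu = rng.uniform(0.0, 2.0)
    rho = rng.uniform(0.1, 1.0)
    t = rng.uniform(0.01, 8.0)
    return lam, mu, rho, t


def random_piecewise_model(rng: np.random.Generator, rho: float | None = None) -> m.RateModel:
    """A random 3-piece model with moderate rates."""
    cps = np.sort(rng.uniform(0.5, 6.0, size=2))
    lams = rng.uniform(0.1, 1.5, size=3)
    mus = rng.uniform(0.0, 1.2, size=3)
    if rho is None:
        rho = rng.uniform(0.3, 1.0)
    return m.make_piecewise_model(cps, lams, mus, rho)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ltt():
    """A tiny hand-made dataset: ages {2, 1}, stem age 3."""
    return m.LTTData([2.0, 1.0], stem_age=3.0)


@pytest.fixture
def two_epoch_example():
    """The worked two-epoch example: old {3, 2}, young {0.5, 0.25}, T = 1."""
    return m.TwoEpochData([3.0, 2.0], [0.5, 0.25])
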