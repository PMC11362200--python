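"""Shared fixtures: random belief generators over every model family."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adosim import (
    Belief,
    ParamGrid,
    make_belief,
    make_exponential_model,
    make_gaussian_toy_pair,
    make_irt_model,
    make_powerlaw_model,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_masses(rng, n):
    m = rng.random(n) + 1e-3
    return m / m.sum()


def random_belief(rng, family: str) -> Belief:
    """A small random belief over the given model family.

    Families: ``irt`` (one model, scalar trait), ``powerlaw``/``exponential``
    (one model, two parameters), ``memory_pair`` (two-model mixture), and
    ``gaussian_toy`` (two real-response models on a shared grid).
    """
    if family == "irt":
        n = rng.integers(3, 12)
        pts = np.sort(rng.uniform(-4, 4, n))
        return make_belief([make_irt_model()], [1.0], [ParamGrid(pts, random_masses(rng, n))])
    if family in ("powerlaw", "exponential"):
        make = make_powerlaw_model if family == "powerlaw" else make_exponential_model
        n = rng.integers(3, 12)
        pts = rng.random((n, 2))
        return make_belief([make()], [1.0], [ParamGrid(pts, random_masses(rng, n))])
    if family == "memory_pair":
        n1, n2 = rng.integers(3, 10, 2)
        g1 = ParamGrid(rng.random((n1, 2)), random_masses(rng, n1))
        g2 = ParamGrid(rng.random((n2, 2)), random_masses(rng, n2))
        return make_belief(
            [make_powerlaw_model(), make_exponential_model()],
            random_masses(rng, 2),
            [g1, g2],
        )
    if family == "gaussian_toy":
        spec_a, spec_b = make_gaussian_toy_pair(grid_halfwidth=40.0, n_grid=41)
        n1, n2 = rng.integers(3, 7, 2)
        g1 = ParamGrid(rng.uniform(-10, 10, n1), random_masses(rng, n1))
        g2 = ParamGrid(rng.uniform(-10, 10, n2), random_masses(rng, n2))
        return make_belief([spec_a, spec_b], random_masses(rng, 2), [g1, g2])
    raise ValueError(family)


def random_stimulus(rng, family: str) -> float:
    if family == "irt":
        return float(rng.uniform(-3, 3))
    if family in ("powerlaw", "exponential", "memory_pair"):
        return float(rng.integers(0, 101))
    return 0.0  # toy models predict at a single stimulus


ALL_FAMILIES = ("irt", "powerlaw", "exponential", "memory_pair", "gaussian_toy")
BINARY_FAMILIES = ("irt", "powerlaw", "exponential", "memory_pair")
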