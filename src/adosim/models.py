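"""Likelihood families used throughout the simulation studies.

Four families are provided:

* a guessing-corrected logistic item-response model linking item difficulty
  ``x`` and proficiency ``theta`` to the probability of a correct answer on a
  multiple-choice item (four response options, so the chance floor is 0.2);
* power-law and exponential forgetting curves for recall probability as a
  function of the delay (seconds) between study and test;
* a pair of toy Gaussian models with a free location parameter and fixed,
  model-specific response noise, used to illustrate model selection with
  real-valued responses.

All families are wrapped in :class:`ModelSpec`, which exposes a scalar
``likelihood`` and a vectorized probability table used by the grid-based
inference machinery.  Real-valued response spaces are handled on a finite
response grid so the same discrete machinery applies to every family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import DomainError

__all__ = [
    "ModelSpec",
    "irt_response_prob",
    "powerlaw_recall_prob",
    "exponential_recall_prob",
    "gaussian_toy_likelihood",
    "make_irt_model",
    "make_powerlaw_model",
    "make_exponential_model",
    "make_gaussian_toy_pair",
    "get_model",
    "register_model",
    "MODEL_REGISTRY",
]

# Constants of the item-response family: a four-alternative forced choice
# yields a guessing floor of .2, leaving a .8 range, with logistic slope 2.72.
IRT_FLOOR = 0.2
IRT_SCALE = 0.8
IRT_SLOPE = 2.72

BINARY_RESPONSES = np.array([0.0, 1.0])


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not np.all(np.isfinite(v)):
            raise DomainError(f"{name} must be finite, got {v!r}")


def irt_response_prob(x, theta):
    """Probability of a correct response to an item of difficulty ``x``.

    ``p(y=1 | x, theta) = .2 + .8 / (1 + exp(-2.72 (theta - x)))``.  Strictly
    increasing in proficiency ``theta``, strictly decreasing in difficulty
    ``x``, and bounded in (0.2, 1.0): however low the proficiency, a guess
    among four options succeeds a fifth of the time.
    """
    _require_finite(x=x, theta=theta)
    return IRT_FLOOR + IRT_SCALE * expit(IRT_SLOPE * (np.asarray(theta) - np.asarray(x)))


def _check_retention_args(x, a, b) -> None:
    _require_finite(x=x, a=a, b=b)
    if np.any(np.asarray(x) < 0):
        raise DomainError(f"delay x must be nonnegative, got {x!r}")
    for name, v in (("a", a), ("b", b)):
        v = np.asarray(v)
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError(f"retention parameter {name} must lie in [0, 1], got {v!r}")


def powerlaw_recall_prob(x, a, b):
    """Power-law forgetting curve ``p(y=1) = a (x + 1)^(-b)``.

    ``a`` is baseline accuracy at zero delay, ``b`` the forgetting rate; both
    lie in [0, 1], so recall probability decays from ``a`` toward 0.
    """
    _check_retention_args(x, a, b)
    return np.asarray(a) * np.power(np.asarray(x, dtype=float) + 1.0, -np.asarray(b))


def exponential_recall_prob(x, a, b):
    """Exponential forgetting curve ``p(y=1) = a exp(-b x)``."""
    _check_retention_args(x, a, b)
    return np.asarray(a) * np.exp(-np.asarray(b) * np.asarray(x, dtype=float))


def gaussian_toy_likelihood(y, mu, sigma):
    """Normal density of a real-valued response around location ``mu``."""
    if not np.all(np.asarray(sigma) > 0):
        raise DomainError(f"sigma must be positive, got {sigma!r}")
    _require_finite(y=y, mu=mu)
    return norm.pdf(np.asarray(y), loc=np.asarray(mu), scale=np.asarray(sigma))


@dataclass(frozen=True)
class ModelSpec:
    """A likelihood family with parameter-space and response-space metadata.

    Parameters
    ----------
    name
        Identifier used in registries, beliefs, and populations.
    param_names
        Labels of the free parameters, in the order they appear in ``theta``.
    param_bounds
        Closed interval per parameter.
    response_space
        Admissible response values.  ``[0, 1]`` for binary families; a finite
        real grid for continuous-response families.
    success_prob
        For binary families: vectorized map ``(x, thetas (G, k)) -> (G,)``
        giving ``p(y=1 | x, theta)``.
    density
        For real-response families: vectorized map
        ``(ys (Y,), x, thetas (G, k)) -> (G, Y)`` of response densities.
    sampler
        Draws one response given ``(x, theta, rng)``; required for
        real-response families (binary families sample from ``success_prob``).
    constants
        Fixed structural constants of the family (documentation/provenance).
    """

    name: str
    param_names: tuple[str, ...]
    param_bounds: tuple[tuple[float, float], ...]
    response_space: np.ndarray
    success_prob: Callable[[float, np.ndarray], np.ndarray] | None = None
    density: Callable[[np.ndarray, float, np.ndarray], np.ndarray] | None = None
    sampler: Callable[[float, np.ndarray, np.random.Generator], float] | None = None
    constants: Mapping[str, float] = field(default_factory=dict)

    @property
    def is_binary(self) -> bool:
        return self.success_prob is not None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def prob_table(self, x, thetas: np.ndarray) -> np.ndarray:
        """Response probability table, shape ``(G, Y)``, rows summing to 1.

        For binary families the columns are ``[p(y=0), p(y=1)]``.  For
        real-response families the density is discretized onto the response
        grid and renormalized, so quadrature error never breaks normalization.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        if self.is_binary:
            p1 = np.asarray(self.success_prob(x, thetas), dtype=float)
            return np.stack([1.0 - p1, p1], axis=-1)
        dens = np.asarray(self.density(self.response_space, x, thetas), dtype=float)
        total = dens.sum(axis=-1, keepdims=True)
        if np.any(total <= 0):
            raise DomainError(f"model {self.name!r}: density vanished on the response grid")
        return dens / total

    def likelihood(self, y, x, theta) -> float:
        """Probability (binary) or density (real) of response ``y``."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if self.is_binary:
            p1 = float(self.success_prob(x, theta[np.newaxis, :])[0])
            return p1 if y == 1 else 1.0 - p1
        return float(self.density(np.atleast_1d(float(y)), x, theta[np.newaxis, :])[0, 0])

    def sample_response(self, x, theta, rng: np.random.Generator):
        """Draw one response from the family at a (continuous) ``theta``."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if self.is_binary:
            p1 = float(self.success_prob(x, theta[np.newaxis, :])[0])
            return int(rng.random() < p1)
        if self.sampler is None:
            raise DomainError(f"model {self.name!r} has no response sampler")
        return float(self.sampler(x, theta, rng))


def make_irt_model(name: str = "irt", bounds: tuple[float, float] = (-10.0, 10.0)) -> ModelSpec:
    """Guessing-corrected logistic item-response model (one proficiency trait)."""

    def success(x, thetas):
        return irt_response_prob(x, thetas[:, 0])

    return ModelSpec(
        name=name,
        param_names=("theta",),
        param_bounds=(bounds,),
        response_space=BINARY_RESPONSES,
        success_prob=success,
        constants={"floor": IRT_FLOOR, "scale": IRT_SCALE, "slope": IRT_SLOPE},
    )


def make_powerlaw_model(name: str = "powerlaw") -> ModelSpec:
    """Power-law retention model with parameters ``(a, b)`` in the unit square."""

    def success(x, thetas):
        return powerlaw_recall_prob(x, thetas[:, 0], thetas[:, 1])

    return ModelSpec(
        name=name,
        param_names=("a", "b"),
        param_bounds=((0.0, 1.0), (0.0, 1.0)),
        response_space=BINARY_RESPONSES,
        success_prob=success,
    )


def make_exponential_model(name: str = "exponential") -> ModelSpec:
    """Exponential retention model with parameters ``(a, b)`` in the unit square."""

    def success(x, thetas):
        return exponential_recall_prob(x, thetas[:, 0], thetas[:, 1])

    return ModelSpec(
        name=name,
        param_names=("a", "b"),
        param_bounds=((0.0, 1.0), (0.0, 1.0)),
        response_space=BINARY_RESPONSES,
        success_prob=success,
    )


def make_gaussian_toy_pair(
    sigma_a: float = 10.0,
    sigma_b: float = 11.0,
    mu_bounds: tuple[float, float] = (-50.0, 50.0),
    grid_center: float = 0.0,
    grid_halfwidth: float | None = None,
    n_grid: int = 1601,
) -> tuple[ModelSpec, ModelSpec]:
    """Two Gaussian location models distinguished only by their response noise.

    Both predict responses at a single stimulus; Model A has standard
    deviation ``sigma_a``, Model B ``sigma_b``.  They share a finite response
    grid (span +/- 8 standard deviations around ``grid_center`` by default) so
    the discrete belief machinery applies unchanged.
    """
    if grid_halfwidth is None:
        grid_halfwidth = 8.0 * max(sigma_a, sigma_b)
    grid = np.linspace(grid_center - grid_halfwidth, grid_center + grid_halfwidth, n_grid)

    def make(name: str, sigma: float) -> ModelSpec:
        def dens(ys, x, thetas):
            return gaussian_toy_likelihood(ys[np.newaxis, :], thetas[:, :1], sigma)

        def sampler(x, theta, rng):
            return rng.normal(theta[0], sigma)

        return ModelSpec(
            name=name,
            param_names=("mu",),
            param_bounds=(mu_bounds,),
            response_space=grid,
            density=dens,
            sampler=sampler,
            constants={"sigma": sigma},
        )

    return make("gaussian_toy_A", sigma_a), make("gaussian_toy_B", sigma_b)


MODEL_REGISTRY: dict[str, Callable[..., ModelSpec]] = {
    "irt": make_irt_model,
    "powerlaw": make_powerlaw_model,
    "exponential": make_exponential_model,
}


def register_model(name: str, factory: Callable[..., ModelSpec]) -> None:
    """Register a user-supplied model factory under ``name``."""
    MODEL_REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> ModelSpec:
    """Instantiate a registered model family by name."""
    if name == "gaussian_toy":
        raise KeyError("use make_gaussian_toy_pair(): the toy models come as a pair")
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model family {name!r}; known: {sorted(MODEL_REGISTRY)}") from None
    return factory(**kwargs)
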