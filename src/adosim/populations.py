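"""Ground-truth participant populations and synthetic response generation.

A :class:`Population` is the data-generating counterpart of a belief: a
mixture over model families with continuous per-parameter densities.  It
carries both continuous samplers (used to draw each simulated participant's
true state, which is never discretized) and a discretized belief-shaped view
(used by the divergence diagnostics, which operate on grids).

Built-in populations cover the simulation studies: Normal proficiency
distributions for the item-response paradigm, and Beta-distributed retention
parameters for the memory paradigms, including the two-model mixtures used
for model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .belief import (
    Belief,
    GridSpec,
    ParamGrid,
    PointMass,
    discretize_joint,
    make_belief,
    parse_density,
)
from .errors import ConfigurationError
from .models import ModelSpec, make_exponential_model, make_irt_model, make_powerlaw_model

__all__ = [
    "Population",
    "GroundTruth",
    "make_population",
    "population_belief",
    "sample_ground_truth",
    "generate_response",
    "IRT_GRID",
    "MEMORY_GRID",
    "POPULATION_REGISTRY",
]

# Default inference grids.  The proficiency grid is wider than the [-3, 3]
# stimulus range so that populations centered at +/-2 are only mildly
# truncated; the memory grid uses cell midpoints of the unit square.
IRT_GRID = GridSpec(-4.0, 4.0, 201, "linspace")
MEMORY_GRID = GridSpec(0.0, 1.0, 51, "midpoint")


@dataclass(frozen=True)
class GroundTruth:
    """A sampled true state of the world: generating model and parameters.

    ``theta`` is the continuous draw from the population density — it is
    never snapped to a grid; only evaluation metrics snap it.
    """

    model_spec: ModelSpec
    theta: np.ndarray

    def __post_init__(self):
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "theta", th)
        for v, (lo, hi) in zip(th, self.model_spec.param_bounds):
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"true parameter {v} outside bounds [{lo}, {hi}] of model "
                    f"{self.model_spec.name!r}"
                )

    @property
    def model_name(self) -> str:
        return self.model_spec.name


@dataclass(frozen=True)
class Population:
    """Ground-truth mixture over models with continuous parameter densities."""

    model_specs: tuple[ModelSpec, ...]
    model_probs: np.ndarray
    param_dists: tuple[tuple, ...]  # per model: tuple of frozen densities
    discretized: Belief

    @property
    def model_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.model_specs)

    def model_index(self, name: str) -> int:
        return self.model_names.index(name)


def population_belief(model_specs, model_probs, density_specs, grid_specs) -> Belief:
    """Discretized belief-shaped view of a population (or a specified prior)."""
    grids = []
    for ms, densities in zip(model_specs, density_specs):
        per_param = list(grid_specs)[: ms.n_params]
        grids.append(discretize_joint(list(densities), per_param))
    return make_belief(model_specs, model_probs, grids)


def _build(model_specs, model_probs, density_specs, grid_specs) -> Population:
    model_specs = tuple(model_specs)
    dists = tuple(tuple(parse_density(d) for d in ds) for ds in density_specs)
    view = population_belief(model_specs, model_probs, dists, grid_specs)
    return Population(
        model_specs=model_specs,
        model_probs=np.asarray(model_probs, dtype=float),
        param_dists=dists,
        discretized=view,
    )


def _irt_pop(mu: float, sigma: float = 1.0, grid: GridSpec = IRT_GRID) -> Population:
    return _build([make_irt_model()], [1.0], [[("normal", mu, sigma)]], [grid])


def _memory_param_pop(b_density, grid: GridSpec = MEMORY_GRID) -> Population:
    return _build(
        [make_powerlaw_model()], [1.0], [[("beta", 1, 1), b_density]], [grid, grid]
    )


def _memory_mixture_pop(pl_densities, exp_densities, grid: GridSpec = MEMORY_GRID) -> Population:
    return _build(
        [make_powerlaw_model(), make_exponential_model()],
        [0.5, 0.5],
        [pl_densities, exp_densities],
        [grid, grid],
    )


POPULATION_REGISTRY = {
    # item-response populations: one proficiency trait
    "irt_standard": lambda: _irt_pop(0.0),
    "irt_low": lambda: _irt_pop(-2.0),
    "irt_high": lambda: _irt_pop(2.0),
    # memory parameter-estimation populations (power-law model only)
    "memory_high_b": lambda: _memory_param_pop(("beta", 2, 1)),
    "memory_low_b": lambda: _memory_param_pop(("beta", 1, 2)),
    # memory model-selection populations (equal-probability two-model mixtures)
    "memory_popA": lambda: _memory_mixture_pop(
        [("beta", 1, 1), ("beta", 1, 1)], [("beta", 1, 1), ("beta", 1, 1)]
    ),
    "memory_popB": lambda: _memory_mixture_pop(
        [("beta", 2, 1), ("beta", 1, 4)], [("beta", 2, 1), ("beta", 1, 80)]
    ),
}


def make_population(spec, grid_specs=None) -> Population:
    """Build a population from a registered name or an explicit description.

    ``spec`` is either a name in :data:`POPULATION_REGISTRY` or a dict with
    keys ``models`` (list of :class:`ModelSpec`), ``probs``, ``densities``
    (per model, per parameter ``(family, *params)`` pairs), and optionally
    ``grids`` (per-parameter :class:`GridSpec` list).
    """
    if isinstance(spec, str):
        try:
            return POPULATION_REGISTRY[spec]()
        except KeyError:
            raise ConfigurationError(
                f"unknown population {spec!r}; known: {sorted(POPULATION_REGISTRY)}"
            ) from None
    if isinstance(spec, Population):
        return spec
    if isinstance(spec, dict):
        grids = spec.get("grids", grid_specs)
        if grids is None:
            raise ConfigurationError("explicit populations need per-parameter grids")
        return _build(spec["models"], spec["probs"], spec["densities"], grids)
    raise ConfigurationError(f"cannot interpret population spec {spec!r}")


def sample_ground_truth(
    population: Population, rng: np.random.Generator, model: str | None = None
) -> GroundTruth:
    """Draw a true state of the world: ``m* ~ model_probs``, ``theta* ~ p0(.|m*)``.

    Pass ``model`` to condition on a generating model (used by studies that
    balance the generating model across experiments instead of randomizing).
    """
    if model is None:
        mi = int(rng.choice(len(population.model_specs), p=population.model_probs))
    else:
        mi = population.model_index(model)
    theta = np.array(
        [_draw(d, rng) for d in population.param_dists[mi]], dtype=float
    )
    return GroundTruth(model_spec=population.model_specs[mi], theta=theta)


def _draw(dist, rng: np.random.Generator) -> float:
    if isinstance(dist, PointMass):
        return dist.value
    return float(dist.rvs(random_state=rng))


def generate_response(model: ModelSpec, theta, x, rng: np.random.Generator):
    """Draw one response from the true likelihood at (continuous) ``theta``."""
    return model.sample_response(x, theta, rng)
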