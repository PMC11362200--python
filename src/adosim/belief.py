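"""Discretized joint beliefs over models and parameters, and Bayes updating.

The belief engine represents the experimenter's specified prior (and every
posterior derived from it) as a finite mixture: a probability per model and,
within each model, a probability mass per point of a parameter grid.  All
integrals elsewhere in the package become exact sums over these atoms.

Continuous priors (Normal, Beta, uniform, point mass) are discretized by
evaluating their density on a grid and renormalizing; mass falling outside
the grid is truncated, with a logged warning when it exceeds 1%.  All logs
are natural, so every information quantity downstream is in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, ImpossibleObservationError
from .models import ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ParamGrid",
    "Belief",
    "PredictiveDist",
    "parse_density",
    "discretize_prior",
    "discretize_joint",
    "make_belief",
    "prior_predictive",
    "model_predictive",
    "bayes_update",
    "bayes_factor",
    "log_posterior_of_truth",
    "belief_to_frame",
    "safe_log",
]

_MASS_TOL = 1e-12
# Positive probabilities below this floor are clamped before taking logs.
_LOG_FLOOR = 1e-300


def safe_log(p: np.ndarray | float) -> np.ndarray | float:
    """Natural log with 0 -> -inf and a clamped floor for tiny positives."""
    p = np.asarray(p, dtype=float)
    tiny = (p > 0) & (p < _LOG_FLOOR)
    if np.any(tiny):
        logger.warning("clamping %d probabilities below %.0e before log", tiny.sum(), _LOG_FLOOR)
        p = np.where(tiny, _LOG_FLOOR, p)
    with np.errstate(divide="ignore"):
        return np.log(p)


# ---------------------------------------------------------------------------
# Density specifications and grids
# ---------------------------------------------------------------------------

class PointMass:
    """Degenerate density concentrated at a single value."""

    def __init__(self, value: float):
        self.value = float(value)

    def pdf(self, x):
        # Indicator up to scale; discretization snaps all mass to the nearest
        # grid point, handled specially in discretize_prior.
        return np.where(np.asarray(x) == self.value, 1.0, 0.0)

    def rvs(self, random_state=None):
        return self.value


def parse_density(spec):
    """Turn a ``(family, *params)`` tuple into a frozen density object.

    Supported families: ``("normal", mu, sigma)``, ``("beta", alpha, beta)``,
    ``("uniform", lo, hi)``, ``("point", value)``.  Frozen scipy distributions
    (anything with ``pdf`` and ``rvs``) pass through unchanged.
    """
    if hasattr(spec, "pdf") and hasattr(spec, "rvs"):
        return spec
    family, *params = spec
    family = family.lower()
    if family == "normal":
        mu, sigma = params
        if sigma <= 0:
            raise DomainError(f"normal sigma must be positive, got {sigma}")
        return stats.norm(loc=mu, scale=sigma)
    if family == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise DomainError(f"beta parameters must be positive, got {params}")
        return stats.beta(a, b)
    if family == "uniform":
        lo, hi = params
        if hi <= lo:
            raise DomainError(f"uniform needs hi > lo, got {params}")
        return stats.uniform(loc=lo, scale=hi - lo)
    if family == "point":
        return PointMass(params[0])
    raise ConfigurationError(f"unknown density family {family!r}")


@dataclass(frozen=True)
class GridSpec:
    """A one-dimensional discretization: ``n`` points on ``[lo, hi]``.

    ``style="linspace"`` includes the endpoints (used for unbounded traits
    such as the item-response proficiency); ``style="midpoint"`` uses the
    midpoints of ``n`` equal cells (used for parameters on a closed interval,
    where endpoint densities may vanish or diverge); ``style="quantile"``
    places points at the quantile midpoints of the prior being discretized,
    giving every atom equal prior mass — the resolution a heavily skewed
    prior (e.g., Beta(1, 80)) needs to be represented faithfully.
    """

    lo: float
    hi: float
    n: int
    style: str = "linspace"

    def points(self, density=None) -> np.ndarray:
        if self.n <= 0:
            raise ConfigurationError("grid point count must be positive")
        if self.style == "linspace":
            return np.linspace(self.lo, self.hi, self.n)
        if self.style == "midpoint":
            edges = np.linspace(self.lo, self.hi, self.n + 1)
            return 0.5 * (edges[:-1] + edges[1:])
        if self.style == "quantile":
            if density is None or not hasattr(density, "ppf"):
                raise ConfigurationError(
                    "quantile grids require a continuous density with a ppf"
                )
            u = (np.arange(self.n) + 0.5) / self.n
            return np.clip(np.asarray(density.ppf(u), dtype=float), self.lo, self.hi)
        raise ConfigurationError(f"unknown grid style {self.style!r}")


@dataclass(frozen=True)
class ParamGrid:
    """An ordered set of parameter vectors with a probability mass each."""

    points: np.ndarray  # (G, k)
    masses: np.ndarray  # (G,)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, np.newaxis]
        m = np.asarray(self.masses, dtype=float)
        if np.any(m < 0):
            raise DomainError("grid masses must be nonnegative")
        total = m.sum()
        if total <= 0:
            raise DomainError("grid masses sum to zero")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "masses", m / total)
        if pts.shape[0] != m.shape[0]:
            raise ConfigurationError("points and masses length mismatch")

    @property
    def n_atoms(self) -> int:
        return self.points.shape[0]

    def nearest_index(self, theta) -> int:
        """Index of the grid point nearest ``theta`` (Euclidean)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        d2 = np.sum((self.points - theta[np.newaxis, :]) ** 2, axis=1)
        return int(np.argmin(d2))


def discretize_prior(density_spec, grid_spec: GridSpec) -> ParamGrid:
    """Discretize a one-dimensional continuous prior onto a grid.

    Masses are proportional to the density at the grid points, renormalized
    to one.  A point mass puts all mass on the nearest grid point.
    """
    dist = parse_density(density_spec)
    if isinstance(dist, PointMass):
        pts = grid_spec.points()
        masses = np.zeros(len(pts))
        masses[int(np.argmin(np.abs(pts - dist.value)))] = 1.0
        return ParamGrid(pts[:, np.newaxis], masses)
    pts = grid_spec.points(dist)
    if grid_spec.style == "quantile":
        return ParamGrid(pts[:, np.newaxis], np.full(len(pts), 1.0 / len(pts)))
    dens = np.asarray(dist.pdf(pts), dtype=float)
    if dens.sum() <= 0:
        raise DomainError("density has zero total mass on the grid")
    if hasattr(dist, "cdf"):
        inside = float(dist.cdf(grid_spec.hi) - dist.cdf(grid_spec.lo))
        if 1.0 - inside > 0.01:
            logger.warning(
                "discretization truncates %.1f%% of the prior mass outside [%g, %g]",
                100 * (1 - inside), grid_spec.lo, grid_spec.hi,
            )
    return ParamGrid(pts[:, np.newaxis], dens)


def discretize_joint(density_specs: Sequence, grid_specs: Sequence[GridSpec]) -> ParamGrid:
    """Independent product of per-parameter priors on a lattice of grid points."""
    if len(density_specs) != len(grid_specs):
        raise ConfigurationError("one grid spec per density spec required")
    grids = [discretize_prior(d, g) for d, g in zip(density_specs, grid_specs)]
    if len(grids) == 1:
        return grids[0]
    axes = [g.points[:, 0] for g in grids]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    masses = grids[0].masses
    for g in grids[1:]:
        masses = np.outer(masses, g.masses).ravel()
    return ParamGrid(points, masses)


# ---------------------------------------------------------------------------
# Belief and predictive distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictiveDist:
    """A probability distribution over the response space."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < -1e-15):
            raise DomainError("predictive probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-10:
            raise DomainError(f"predictive probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))

    def prob_of(self, y) -> float:
        return float(self.probs[_response_index(self.support, y)])


def _response_index(support: np.ndarray, y) -> int:
    """Index of response ``y`` in the support (nearest point for real grids)."""
    return int(np.argmin(np.abs(support - float(y))))


@dataclass(frozen=True)
class Belief:
    """Joint distribution over models and discretized parameters.

    ``model_probs[i]`` is the probability of ``model_specs[i]``;
    ``param_grids[i]`` the within-model parameter distribution.  All model
    specs must share a response space so predictive distributions are
    comparable across models.
    """

    model_specs: tuple[ModelSpec, ...]
    model_probs: np.ndarray
    param_grids: tuple[ParamGrid, ...]

    def __post_init__(self):
        p = np.asarray(self.model_probs, dtype=float)
        if len(self.model_specs) != len(p) or len(self.param_grids) != len(p):
            raise ConfigurationError("model_specs, model_probs, param_grids must align")
        if np.any(p < 0) or abs(p.sum() - 1.0) > _MASS_TOL:
            p = np.clip(p, 0, None)
            total = p.sum()
            if total <= 0:
                raise DomainError("model probabilities sum to zero")
            p = p / total
        object.__setattr__(self, "model_probs", p)
        object.__setattr__(self, "model_specs", tuple(self.model_specs))
        object.__setattr__(self, "param_grids", tuple(self.param_grids))
        names = [m.name for m in self.model_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate model names: {names}")
        for i, (ms, g) in enumerate(zip(self.model_specs, self.param_grids)):
            if g.points.shape[1] != ms.n_params:
                raise ConfigurationError(f"grid dimension mismatch for model {ms.name!r}")
        ref = self.model_specs[0].response_space
        for ms in self.model_specs[1:]:
            if ms.response_space.shape != ref.shape or not np.allclose(ms.response_space, ref):
                raise ConfigurationError("all models in a belief must share a response space")

    @property
    def response_space(self) -> np.ndarray:
        return self.model_specs[0].response_space

    @property
    def model_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.model_specs)

    def model_index(self, name: str) -> int:
        try:
            return self.model_names.index(name)
        except ValueError:
            raise KeyError(f"model {name!r} not in belief ({self.model_names})") from None

    @property
    def single_model(self) -> bool:
        return len(self.model_specs) == 1


def make_belief(model_specs, model_probs, param_grids) -> Belief:
    """Convenience constructor accepting lists and plain sequences."""
    return Belief(tuple(model_specs), np.asarray(model_probs, dtype=float), tuple(param_grids))


def prior_predictive(belief: Belief, x) -> PredictiveDist:
    """Marginal response distribution ``p(y|x)`` under the belief.

    ``p(y|x) = sum_m p(m) sum_theta p(y|x,theta,m) p(theta|m)``.
    """
    probs = np.zeros(len(belief.response_space))
    for pm, ms, grid in zip(belief.model_probs, belief.model_specs, belief.param_grids):
        if pm == 0:
            continue
        table = ms.prob_table(x, grid.points)  # (G, Y)
        probs += pm * (grid.masses @ table)
    return PredictiveDist(belief.response_space, probs)


def model_predictive(belief: Belief, m: str, x) -> PredictiveDist:
    """Focal predictive ``p(y|x,m)``: the response distribution of one model
    under its current (specified) parameter distribution."""
    i = belief.model_index(m)
    table = belief.model_specs[i].prob_table(x, belief.param_grids[i].points)
    return PredictiveDist(belief.response_space, belief.param_grids[i].masses @ table)


def _likelihood_columns(belief: Belief, x, y) -> list[np.ndarray]:
    """Per-model likelihood of response ``y`` at each grid atom."""
    yi = _response_index(belief.response_space, y)
    cols = []
    for ms, grid in zip(belief.model_specs, belief.param_grids):
        cols.append(ms.prob_table(x, grid.points)[:, yi])
    return cols


def bayes_update(belief: Belief, x, y) -> Belief:
    """Posterior belief after observing response ``y`` to stimulus ``x``.

    The input belief is unmodified; joint masses are multiplied by the
    likelihood and renormalized, updating both the model marginals and the
    within-model grids.  Raises :class:`ImpossibleObservationError` when the
    observed response has zero marginal probability.
    """
    cols = _likelihood_columns(belief, x, y)
    return _update_with_columns(belief, cols, context=f"x={x!r}, y={y!r}")


def _update_with_columns(belief: Belief, cols, context: str = "") -> Belief:
    model_weights = np.empty(len(belief.model_specs))
    new_grids = []
    for i, (pm, grid, lik) in enumerate(zip(belief.model_probs, belief.param_grids, cols)):
        joint = grid.masses * lik
        total = joint.sum()
        model_weights[i] = pm * total
        if total > 0:
            new_grids.append(replace(grid, masses=joint / total))
        else:
            new_grids.append(grid)  # conditional masses undefined; prob -> 0
    z = model_weights.sum()
    if z <= 0:
        raise ImpossibleObservationError(
            f"observation has zero probability under the belief ({context})"
        )
    return Belief(belief.model_specs, model_weights / z, tuple(new_grids))


def bayes_factor(belief: Belief, m1: str, m2: str, x, y) -> float:
    """Ratio of marginal likelihoods ``p(y|x,m1) / p(y|x,m2)``.

    Each marginal likelihood averages the response likelihood over the
    model's specified parameter prior, so the Bayes factor inherits any
    misinformation in those priors.
    """
    num = model_predictive(belief, m1, x).prob_of(y)
    den = model_predictive(belief, m2, x).prob_of(y)
    if den <= 0:
        raise DomainError(f"zero marginal likelihood of y={y!r} under model {m2!r}")
    return num / den


def log_posterior_of_truth(belief: Belief, truth, focus) -> float:
    """Natural-log posterior probability of the true focal value.

    ``truth`` carries the generating model and (continuous) parameter value;
    the parameter is snapped to the nearest grid point of its model's grid.
    Returns ``-inf`` (never raises) when the mass at the truth is zero.
    """
    kind = getattr(focus, "kind", focus)
    i = belief.model_index(truth.model_name)
    if kind == "model":
        p = float(belief.model_probs[i])
    elif kind == "parameter":
        grid = belief.param_grids[i]
        p = float(grid.masses[grid.nearest_index(truth.theta)])
    elif kind == "joint":
        grid = belief.param_grids[i]
        p = float(belief.model_probs[i] * grid.masses[grid.nearest_index(truth.theta)])
    else:
        raise ConfigurationError(f"unknown focus kind {kind!r}")
    return float(safe_log(p)) if p > 0 else -np.inf


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def belief_to_frame(belief: Belief) -> pd.DataFrame:
    """Tabular view: one row per joint atom (model, parameter values, mass)."""
    rows = []
    for pm, ms, grid in zip(belief.model_probs, belief.model_specs, belief.param_grids):
        df = pd.DataFrame(grid.points, columns=list(ms.param_names))
        df.insert(0, "model", ms.name)
        df["mass"] = pm * grid.masses
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def belief_from_frame(frame: pd.DataFrame, model_specs: Sequence[ModelSpec]) -> Belief:
    """Rebuild a belief from the tabular layout of :func:`belief_to_frame`."""
    specs = {m.name: m for m in model_specs}
    probs, grids, ordered = [], [], []
    for name, sub in frame.groupby("model", sort=False):
        ms = specs[name]
        pts = sub[list(ms.param_names)].to_numpy(dtype=float)
        mass = sub["mass"].to_numpy(dtype=float)
        probs.append(mass.sum())
        grids.append(ParamGrid(pts, mass))
        ordered.append(ms)
    return make_belief(ordered, probs, grids)
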