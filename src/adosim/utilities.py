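"""Information-theoretic global utilities that score candidate stimuli.

The global utility of a stimulus is the mutual information, under the
specified prior, between the *focus* of inference and the response:

    U(x) = I(Phi; Y | x)
         = sum_phi sum_y p(phi) p(y|x,phi) log( p(phi|y,x) / p(phi) ).

The focus is the parameter (parameter estimation, single model), the model
(model selection), or the joint model-parameter state (total entropy).  Two
independent routes are provided: :func:`global_mi_utility` evaluates the
double sum directly over grid atoms and responses, while
:func:`utility_kl_form` rewrites the same quantity as the expected
Kullback-Leibler divergence from focal posterior to focal prior, computed
via fresh hypothetical Bayes updates.  Agreement of the two routes is a
standing test of the machinery.  All values are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, xlogy

from .belief import Belief, bayes_update, prior_predictive
from .errors import ConfigurationError, ImpossibleObservationError

__all__ = [
    "FocusSpec",
    "PARAMETER",
    "MODEL",
    "JOINT",
    "UtilityReport",
    "global_mi_utility",
    "utility_kl_form",
    "total_entropy_utility",
    "mi_scores",
    "focal_probs",
    "likelihood_tables",
    "utility_curve",
]


@dataclass(frozen=True)
class FocusSpec:
    """The focal quantity scored by the utility: parameter, model, or joint."""

    kind: str

    def __post_init__(self):
        if self.kind not in ("parameter", "model", "joint"):
            raise ConfigurationError(f"unknown focus kind {self.kind!r}")


PARAMETER = FocusSpec("parameter")
MODEL = FocusSpec("model")
JOINT = FocusSpec("joint")


@dataclass(frozen=True)
class UtilityReport:
    """A scored candidate stimulus."""

    stimulus: float
    value: float  # nats
    focus: FocusSpec


def _check_focus(belief: Belief, focus: FocusSpec) -> FocusSpec:
    if isinstance(focus, str):
        focus = FocusSpec(focus)
    if focus.kind == "parameter" and not belief.single_model:
        raise ConfigurationError("parameter focus requires a single-model belief")
    return focus


class LikelihoodTables:
    """Per-model response-probability tensors ``(C, G, Y)`` over candidates.

    The tensors depend only on the model specs, the candidate stimuli, and
    the grid *points* (not the masses), so they can be computed once per
    experiment and reused across trials.  The per-atom term
    ``sum_y p(y|x,phi) log p(y|x,phi)`` is equally mass-independent and is
    cached on first use by the utility scorer.
    """

    def __init__(self, tables: list[np.ndarray]):
        self.tables = tables
        self._tlogt: list[np.ndarray] | None = None

    def __iter__(self):
        return iter(self.tables)

    def __getitem__(self, i):
        return self.tables[i]

    def tlogt(self) -> list[np.ndarray]:
        if self._tlogt is None:
            self._tlogt = [xlogy(t, t).sum(axis=2) for t in self.tables]
        return self._tlogt


def likelihood_tables(belief: Belief, xs) -> LikelihoodTables:
    """Build :class:`LikelihoodTables` for a belief over candidate stimuli."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    tables = []
    for ms, grid in zip(belief.model_specs, belief.param_grids):
        tables.append(np.stack([ms.prob_table(x, grid.points) for x in xs]))
    return LikelihoodTables(tables)


def mi_scores(belief: Belief, xs, focus: FocusSpec, tables=None) -> np.ndarray:
    """Mutual-information utility at each candidate stimulus, vectorized.

    Direct double sum over focal values and responses: each atom contributes
    ``p(phi) p(y|x,phi) log( p(y|x,phi) / p(y|x) )``, which is the local
    utility ``log(p(phi|y,x)/p(phi))`` weighted by ``p(y|x,phi) p(phi)``.
    """
    focus = _check_focus(belief, focus)
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if tables is None:
        tables = likelihood_tables(belief, xs)
    n_c = len(xs)

    if focus.kind == "model":
        preds = [np.einsum("cgy,g->cy", t_m, g.masses)
                 for t_m, g in zip(tables, belief.param_grids)]
        py = sum(pm * pred for pm, pred in zip(belief.model_probs, preds))
        scores = np.zeros(n_c)
        for pm, pred in zip(belief.model_probs, preds):
            if pm > 0:
                scores += pm * rel_entr(pred, py).sum(axis=1)
        return scores

    # Parameter or joint focus: the foci are the grid atoms themselves.  The
    # double sum  sum_phi sum_y  p(phi) p(y|phi) [log p(y|phi) - log p(y)]
    # is accumulated with its mass-independent first part taken from the
    # cached tables.
    if not isinstance(tables, LikelihoodTables):
        tables = LikelihoodTables(list(tables))
    preds = [np.einsum("cgy,g->cy", t_m, g.masses)
             for t_m, g in zip(tables, belief.param_grids)]
    py = sum(pm * pred for pm, pred in zip(belief.model_probs, preds))
    log_py = np.where(py > 0, np.log(np.clip(py, 1e-300, None)), 0.0)
    scores = np.zeros(n_c)
    for pm, tlt, pred, g in zip(belief.model_probs, tables.tlogt(), preds, belief.param_grids):
        if pm > 0:
            scores += pm * (tlt @ g.masses - (pred * log_py).sum(axis=1))
    return scores


def global_mi_utility(belief: Belief, x, focus: FocusSpec) -> UtilityReport:
    """Global mutual-information utility ``U(x) = I(Phi; Y|x)`` in nats."""
    focus = _check_focus(belief, focus)
    value = float(mi_scores(belief, [x], focus)[0])
    return UtilityReport(stimulus=float(x), value=value, focus=focus)


def focal_probs(belief: Belief, focus: FocusSpec) -> np.ndarray:
    """The distribution over focal values implied by a belief."""
    focus = _check_focus(belief, focus)
    if focus.kind == "model":
        return np.asarray(belief.model_probs, dtype=float)
    if focus.kind == "parameter":
        return np.asarray(belief.param_grids[0].masses, dtype=float)
    return np.concatenate(
        [pm * g.masses for pm, g in zip(belief.model_probs, belief.param_grids)]
    )


def utility_kl_form(belief: Belief, x, focus: FocusSpec) -> UtilityReport:
    """The utility as expected focal divergence under the prior predictive.

    ``U(x) = sum_y D_KL( Phi|y,x || Phi ) p(y|x)``, with the focal posterior
    obtained by a fresh hypothetical Bayes update per candidate response.
    Deliberately shares no inner loop with :func:`global_mi_utility`.
    """
    focus = _check_focus(belief, focus)
    prior_focal = focal_probs(belief, focus)
    pred = prior_predictive(belief, x)
    value = 0.0
    for y, p_y in zip(pred.support, pred.probs):
        if p_y <= 0:
            continue
        post = bayes_update(belief, x, y)
        value += p_y * float(rel_entr(focal_probs(post, focus), prior_focal).sum())
    return UtilityReport(stimulus=float(x), value=float(value), focus=focus)


def total_entropy_utility(belief: Belief, x) -> UtilityReport:
    """Utility that takes the entire state of the world (m, theta) as focus.

    Scores reduction of uncertainty about the joint model-parameter state,
    balancing model discrimination against parameter refinement.
    """
    return global_mi_utility(belief, x, JOINT)


def utility_curve(belief: Belief, xs, focus: FocusSpec, utility: str = "mi"):
    """Utility at each candidate stimulus, as a table for plotting.

    Returns a pandas DataFrame with columns ``stimulus``, ``utility`` (nats),
    and ``focus``.
    """
    import pandas as pd

    focus = JOINT if utility == "total_entropy" else _check_focus(belief, focus)
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    values = mi_scores(belief, xs, focus)
    return pd.DataFrame({"stimulus": xs, "utility": values, "focus": focus.kind})
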