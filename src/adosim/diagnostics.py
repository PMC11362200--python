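"""Population-aware diagnostics for adaptive design under prior misinformation.

The global utility weighs focal divergences by the *specified* prior
predictive; what an experiment actually delivers depends on the *population*
response distribution.  The expected focal divergence replaces the weights:

    U1(x) = sum_y D_KL( Phi_1|y,x || Phi_1 ) p0(y|x),

where subscript 1 marks the specified belief and subscript 0 the population.
It decomposes exactly into three interpretable terms:

    U1(x) = H(Y0|x)                      (response variability)
          + D_KL( Y0|x || Y1|x )         (surprisal)
          + E_0[ E_1[ log p1(y|x,phi) | y ] ]   (hindsight, typically < 0)

Response variability is the entropy of the population's responses; surprisal
measures how much the population surprises the specified predictive;
hindsight is the expected posterior log-likelihood of responses under the
specified prior, rewarding priors that respond to data.  Each term is
computed from its own formula — the identity with the direct route is a
numerical check, not a definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr, xlogy

from .belief import Belief, PredictiveDist, bayes_update, model_predictive, prior_predictive
from .errors import ConfigurationError
from .utilities import FocusSpec, _check_focus, focal_probs, global_mi_utility

__all__ = [
    "DecompositionReport",
    "response_entropy",
    "kl_divergence",
    "expected_focal_divergence",
    "decompose_efd",
    "decomposition_curve",
]


@dataclass(frozen=True)
class DecompositionReport:
    """Per-stimulus decomposition of the expected focal divergence (nats)."""

    stimulus: float
    response_variability: float
    surprisal: float
    hindsight: float
    expected_focal_divergence: float
    specified_global_utility: float


def response_entropy(dist: PredictiveDist) -> float:
    """Shannon entropy ``-sum p log p`` in nats, with ``0 log 0 = 0``."""
    return float(-xlogy(dist.probs, dist.probs).sum())


def kl_divergence(p: PredictiveDist, q: PredictiveDist) -> float:
    """``D_KL(p || q) = sum p log(p/q)`` in nats over a shared support."""
    if p.support.shape != q.support.shape or not np.allclose(p.support, q.support):
        raise ConfigurationError("KL divergence requires a shared support")
    if np.any((p.probs > 0) & (q.probs <= 0)):
        raise ConfigurationError("absolute continuity violated: q = 0 where p > 0")
    return float(rel_entr(p.probs, q.probs).sum())


def _check_compatible(belief: Belief, population) -> Belief:
    """Population's discretized belief view, after registry checks."""
    view = population.discretized if hasattr(population, "discretized") else population
    if view.model_names != belief.model_names:
        raise ConfigurationError(
            f"belief models {belief.model_names} do not match population models "
            f"{view.model_names}"
        )
    if view.response_space.shape != belief.response_space.shape or not np.allclose(
        view.response_space, belief.response_space
    ):
        raise ConfigurationError("belief and population must share a response space")
    return view


def expected_focal_divergence(belief: Belief, population, x, focus: FocusSpec) -> float:
    """Expected focal divergence ``U1(x)`` in nats.

    The inner KL divergence (focal posterior vs. focal prior) uses the
    specified belief; the outer expectation weights responses by the
    population predictive ``p0(y|x)``.  When the population's discretized
    view coincides with the belief this reduces to the global utility.
    """
    focus = _check_focus(belief, focus)
    view = _check_compatible(belief, population)
    p0 = prior_predictive(view, x)
    prior_focal = focal_probs(belief, focus)
    value = 0.0
    for y, w in zip(p0.support, p0.probs):
        if w <= 0:
            continue
        post = bayes_update(belief, x, y)
        value += w * float(rel_entr(focal_probs(post, focus), prior_focal).sum())
    return float(value)


def _focal_predictives(belief: Belief, x, focus: FocusSpec) -> np.ndarray:
    """Matrix ``p1(y|x,phi)`` of focal predictives, shape (n_phi, Y)."""
    if focus.kind == "model":
        return np.stack(
            [model_predictive(belief, name, x).probs for name in belief.model_names]
        )
    tables = [ms.prob_table(x, g.points) for ms, g in zip(belief.model_specs, belief.param_grids)]
    return np.concatenate(tables, axis=0)  # parameter focus: single model


def decompose_efd(belief: Belief, population, x, focus: FocusSpec) -> DecompositionReport:
    """Three-term decomposition of the expected focal divergence at ``x``.

    Each term is evaluated from its defining formula; the report also carries
    the directly computed expected focal divergence and the specified global
    utility for comparison.
    """
    focus = _check_focus(belief, focus)
    view = _check_compatible(belief, population)
    p0 = prior_predictive(view, x)
    p1 = prior_predictive(belief, x)

    variability = response_entropy(p0)
    surprisal = kl_divergence(p0, p1)

    preds = _focal_predictives(belief, x, focus)  # (n_phi, Y)
    hindsight = 0.0
    for yi, (y, w) in enumerate(zip(p0.support, p0.probs)):
        if w <= 0:
            continue
        post_focal = focal_probs(bayes_update(belief, x, y), focus)
        hindsight += w * float(xlogy(post_focal, preds[:, yi]).sum())

    return DecompositionReport(
        stimulus=float(x),
        response_variability=variability,
        surprisal=surprisal,
        hindsight=float(hindsight),
        expected_focal_divergence=expected_focal_divergence(belief, population, x, focus),
        specified_global_utility=global_mi_utility(belief, x, focus).value,
    )


def decomposition_curve(belief: Belief, population, xs, focus: FocusSpec) -> pd.DataFrame:
    """Decomposition at each candidate stimulus, as a table for plotting."""
    rows = [decompose_efd(belief, population, x, focus) for x in np.atleast_1d(xs)]
    return pd.DataFrame([r.__dict__ for r in rows])
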