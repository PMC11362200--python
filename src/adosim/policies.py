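"""Design policies and the single-experiment loop.

Each simulated experiment repeats one cycle per trial: select a stimulus
(either adaptively, by maximizing a global utility under the current belief,
or from a fixed randomized schedule), draw a response from the true
data-generating likelihood, Bayes-update the belief, and record the log
posterior probability of the true focal value.

The adaptive policy recomputes utilities for every candidate on every trial
— the belief changes, so nothing can be cached across trials — but the
per-model likelihood tensors over the candidate set depend only on the grid
points and are computed once per experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief import Belief, _response_index, _update_with_columns, log_posterior_of_truth
from .errors import ConfigurationError, ImpossibleObservationError
from .populations import GroundTruth, generate_response
from .utilities import FocusSpec, UtilityReport, _check_focus, likelihood_tables, mi_scores, JOINT

__all__ = [
    "DesignSpace",
    "TrialRecord",
    "ExperimentTrace",
    "ado_select",
    "fixed_schedule",
    "run_experiment",
    "trace_to_frame",
    "config_digest",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class DesignSpace:
    """The ordered set of admissible stimuli."""

    candidates: np.ndarray

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.candidates, dtype=float))
        if c.size == 0:
            raise ConfigurationError("design space must be nonempty")
        if len(np.unique(c)) != len(c):
            raise ConfigurationError("design space must not contain duplicates")
        object.__setattr__(self, "candidates", c)


@dataclass(frozen=True)
class TrialRecord:
    """One pass of the experiment loop (1-based trial index)."""

    index: int
    stimulus: float
    response: float
    chosen_utility: float  # nats; NaN under the fixed design
    log_post_truth: float  # metric after the trial's Bayes update


@dataclass(frozen=True)
class ExperimentTrace:
    """Full record of one simulated experiment."""

    records: tuple[TrialRecord, ...]
    ground_truth: GroundTruth
    config_digest: str
    seed: int | None
    focus: FocusSpec
    final_belief: Belief

    @property
    def metrics(self) -> np.ndarray:
        return np.array([r.log_post_truth for r in self.records])


def config_digest(config: dict) -> str:
    """Short stable digest of a configuration mapping, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _candidate_scores(belief, design_space, utility, focus, tables):
    if callable(utility):
        vals = []
        for x in design_space.candidates:
            u = utility(belief, x, focus)
            vals.append(u.value if isinstance(u, UtilityReport) else float(u))
        return np.asarray(vals, dtype=float)
    if utility == "mi":
        return mi_scores(belief, design_space.candidates, focus, tables=tables)
    if utility == "total_entropy":
        return mi_scores(belief, design_space.candidates, JOINT, tables=tables)
    raise ConfigurationError(f"unknown utility {utility!r}")


def ado_select(
    belief: Belief,
    design_space: DesignSpace,
    utility="mi",
    focus: FocusSpec | str = "parameter",
    tables=None,
) -> float:
    """Stimulus maximizing the global utility over the candidate set.

    Exact ties (within 1e-12 nats) are broken deterministically in favor of
    the smallest stimulus value.
    """
    focus = _check_focus(belief, focus)
    scores = _candidate_scores(belief, design_space, utility, focus, tables)
    best = scores.max()
    return float(design_space.candidates[scores >= best - _TIE_TOL].min())


def fixed_schedule(stimuli, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of a multiset of stimuli."""
    return rng.permutation(np.asarray(stimuli, dtype=float))


def run_experiment(
    policy: str,
    belief: Belief,
    truth: GroundTruth,
    design,
    n_trials: int,
    rng: np.random.Generator,
    focus: FocusSpec | str = "parameter",
    utility="mi",
    digest: str = "",
    seed: int | None = None,
    tables=None,
) -> ExperimentTrace:
    """Run one simulated experiment and return its trace.

    ``policy`` is ``"ado"`` (``design`` is a :class:`DesignSpace`) or
    ``"fixed"`` (``design`` is an ordered schedule of length >= ``n_trials``).
    Both policies start from the same specified prior ``belief``; the
    posterior after each trial is the prior on the next.
    """
    focus = _check_focus(belief, focus)
    if policy == "ado":
        space = design if isinstance(design, DesignSpace) else DesignSpace(design)
        candidates = space.candidates
    elif policy == "fixed":
        schedule = np.atleast_1d(np.asarray(design, dtype=float))
        if len(schedule) < n_trials:
            raise ConfigurationError(
                f"fixed schedule has {len(schedule)} stimuli < {n_trials} trials"
            )
        candidates = np.unique(schedule)
        space = None
    else:
        raise ConfigurationError(f"unknown policy {policy!r}")

    # Likelihood tensors over the candidate set: grid points never change
    # within an experiment, only masses do.  Callers running many experiments
    # with the same prior and candidates may pass them in precomputed.
    if tables is None:
        tables = likelihood_tables(belief, candidates)
    cand_index = {float(x): i for i, x in enumerate(candidates)}

    records = []
    for t in range(1, n_trials + 1):
        if policy == "ado":
            scores = _candidate_scores(belief, space, utility, focus, tables)
            best = scores.max()
            # deterministic tie-break: smallest stimulus among the tied
            tied = np.flatnonzero(scores >= best - _TIE_TOL)
            ci = int(tied[np.argmin(candidates[tied])])
            x = float(candidates[ci])
            chosen_utility = float(scores[ci])
        else:
            x = float(schedule[t - 1])
            ci = cand_index[x]
            chosen_utility = float("nan")

        y = generate_response(truth.model_spec, truth.theta, x, rng)
        yi = _response_index(belief.response_space, y)
        cols = [tab[ci, :, yi] for tab in tables]
        try:
            belief = _update_with_columns(belief, cols, context=f"x={x}, y={y}")
        except ImpossibleObservationError as err:
            raise ImpossibleObservationError(f"trial {t}: {err}") from err
        records.append(
            TrialRecord(
                index=t,
                stimulus=x,
                response=float(y),
                chosen_utility=chosen_utility,
                log_post_truth=log_posterior_of_truth(belief, truth, focus),
            )
        )

    return ExperimentTrace(
        records=tuple(records),
        ground_truth=truth,
        config_digest=digest,
        seed=seed,
        focus=focus,
        final_belief=belief,
    )


def trace_to_frame(trace: ExperimentTrace) -> pd.DataFrame:
    """Tabular view of a trace: one row per trial, with provenance columns."""
    df = pd.DataFrame([r.__dict__ for r in trace.records])
    df["config_digest"] = trace.config_digest
    df["seed"] = trace.seed
    return df
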