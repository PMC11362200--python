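"""Drivers for the simulation studies and trace aggregation.

Three factorial studies are provided, each crossing design methods (adaptive
vs. fixed randomized schedules) with populations and specified priors:

* **Item response**: estimating a proficiency trait with the
  guessing-corrected logistic model.  31 candidate difficulties on [-3, 3],
  31 trials.  Three condition sets vary (i) the population under a fixed
  N(0, 1) prior, (ii) the prior under a N(2, 1) population ("uncontrolled"
  changes), and (iii) the prior under a N(0, 1) population ("controlled"
  changes, including the matched-support N(0, .65) prior).
* **Memory retention, parameter estimation**: the power-law forgetting
  curve with Beta-distributed (a, b).  Fixed design: ten classic delays
  repeated ten times in random order; adaptive design: any integer delay in
  [0, 100].  100 trials.  Four prior types per population: informative,
  misinformative (populations swapped), uninformative in parameter space,
  and uninformative in data space.
* **Memory retention, model selection**: power-law vs. exponential
  forgetting, equal model probabilities, generating model balanced across
  experiments.  Priors A (uninformative in parameter space) and B
  (uninformative in data space), each informative for its own population.

Every experiment replays in isolation: a master seed and the experiment's
global index deterministically derive its generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .belief import Belief, GridSpec
from .errors import ConfigurationError
from .models import make_exponential_model, make_irt_model, make_powerlaw_model
from .policies import DesignSpace, ExperimentTrace, config_digest, fixed_schedule, run_experiment
from .populations import (
    IRT_GRID,
    MEMORY_GRID,
    Population,
    make_population,
    population_belief,
    sample_ground_truth,
)
from .utilities import FocusSpec, likelihood_tables

__all__ = [
    "StudyCell",
    "StudyPlan",
    "StudyResult",
    "LearningCurve",
    "aggregate_traces",
    "irt_prior",
    "memory_param_prior",
    "memory_selection_prior",
    "make_irt_plan",
    "make_memory_param_plan",
    "make_memory_selection_plan",
    "run_plan",
    "run_irt_study",
    "run_memory_param_study",
    "run_memory_model_selection_study",
    "IRT_CANDIDATES",
    "MEMORY_FIXED_DELAYS",
    "MEMORY_CANDIDATES",
]

# Stimulus banks.
IRT_CANDIDATES = np.linspace(-3.0, 3.0, 31)
MEMORY_FIXED_DELAYS = np.array([0, 1, 2, 4, 7, 12, 21, 35, 59, 99], dtype=float)
MEMORY_CANDIDATES = np.arange(0, 101, dtype=float)


# ---------------------------------------------------------------------------
# Specified-prior builders
# ---------------------------------------------------------------------------

def irt_prior(mu: float, sigma: float, grid: GridSpec = IRT_GRID) -> Belief:
    """Single-model item-response belief with a Normal proficiency prior."""
    return population_belief([make_irt_model()], [1.0], [[("normal", mu, sigma)]], [grid])


def memory_param_prior(a_density, b_density, grid: GridSpec = MEMORY_GRID) -> Belief:
    """Power-law-only belief with independent Beta priors on (a, b)."""
    return population_belief(
        [make_powerlaw_model()], [1.0], [[a_density, b_density]], [grid, grid]
    )


# Model-selection beliefs discretize each parameter at the quantile midpoints
# of its own prior (equal mass per atom): a uniform lattice cannot resolve the
# Beta(1, 80) forgetting-rate prior of the exponential model under prior B.
MEMORY_SELECTION_GRID = GridSpec(0.0, 1.0, 51, "quantile")


def memory_selection_prior(
    pl_densities, exp_densities, grid: GridSpec = MEMORY_SELECTION_GRID
) -> Belief:
    """Two-model belief (power-law, exponential) with equal model probabilities."""
    return population_belief(
        [make_powerlaw_model(), make_exponential_model()],
        [0.5, 0.5],
        [pl_densities, exp_densities],
        [grid, grid],
    )


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyCell:
    """One fully specified condition: method x population x prior (x model)."""

    labels: dict
    method: str  # "ado" | "fixed"
    prior: Belief
    population: Population
    focus: FocusSpec
    design_space: DesignSpace | None = None  # for ado
    schedule_base: np.ndarray | None = None  # for fixed; permuted per experiment
    generating_model: str | None = None
    utility: str = "mi"


@dataclass(frozen=True)
class StudyPlan:
    """A factorial study: cells x repetitions, with a master seed."""

    cells: tuple[StudyCell, ...]
    reps: int
    n_trials: int
    master_seed: int
    name: str = "study"

    @property
    def n_experiments(self) -> int:
        return len(self.cells) * self.reps

    def digest(self) -> str:
        desc = {
            "name": self.name,
            "reps": self.reps,
            "n_trials": self.n_trials,
            "master_seed": self.master_seed,
            "cells": [c.labels | {"method": c.method} for c in self.cells],
        }
        return config_digest(desc)


@dataclass(frozen=True)
class LearningCurve:
    """Per-trial mean and standard error of the log posterior of the truth."""

    trials: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray  # traces contributing per trial (after -inf exclusion)
    n_excluded: np.ndarray  # -inf sentinels excluded per trial
    degenerate_n: bool  # True when any trial has fewer than two contributors


def aggregate_traces(traces: Sequence[ExperimentTrace]) -> LearningCurve:
    """Pool traces into a learning curve (mean +/- SE per trial).

    Standard error is sample SD / sqrt(n).  ``-inf`` metric values (zero
    posterior mass at the truth) are excluded from the means, with the
    per-trial exclusion count reported.
    """
    if not traces:
        t = np.array([], dtype=int)
        return LearningCurve(t, t.astype(float), t.astype(float), t, t, True)
    lengths = {len(tr.records) for tr in traces}
    if len(lengths) != 1:
        raise ConfigurationError(f"traces have mixed trial counts: {sorted(lengths)}")
    metrics = np.stack([tr.metrics for tr in traces])  # (N, T)
    finite = np.isfinite(metrics)
    n = finite.sum(axis=0)
    n_excluded = metrics.shape[0] - n
    masked = np.where(finite, metrics, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, masked.sum(axis=0) / np.maximum(n, 1), np.nan)
        dev2 = np.where(finite, (metrics - mean[np.newaxis, :]) ** 2, 0.0)
        sd = np.sqrt(dev2.sum(axis=0) / np.maximum(n - 1, 1))
        se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return LearningCurve(
        trials=np.arange(1, metrics.shape[1] + 1),
        mean=mean,
        se=se,
        n=n,
        n_excluded=n_excluded,
        degenerate_n=bool(np.any(n < 2)),
    )


def _irt_cells(condition_sets=None) -> list[StudyCell]:
    prior_n01 = irt_prior(0.0, 1.0)
    sets = {
        "population": [
            (pop, "N(0,1)", prior_n01)
            for pop in ("irt_standard", "irt_low", "irt_high")
        ],
        "prior_uncontrolled": [
            ("irt_high", label, irt_prior(mu, sigma))
            for label, mu, sigma in (
                ("N(2,1)", 2.0, 1.0),
                ("N(0,1)", 0.0, 1.0),
                ("N(0,2)", 0.0, 2.0),
            )
        ],
        "prior_controlled": [
            ("irt_standard", label, irt_prior(mu, sigma))
            for label, mu, sigma in (
                ("N(0,1)", 0.0, 1.0),
                ("N(0,.65)", 0.0, 0.65),
                ("N(0,2)", 0.0, 2.0),
            )
        ],
    }
    if condition_sets is not None:
        sets = {k: sets[k] for k in condition_sets}
    cells = []
    for set_name, combos in sets.items():
        for pop_name, prior_label, prior in combos:
            pop = make_population(pop_name)
            for method in ("ado", "fixed"):
                cells.append(
                    StudyCell(
                        labels={
                            "condition_set": set_name,
                            "population": pop_name,
                            "prior": prior_label,
                            "method": method,
                        },
                        method=method,
                        prior=prior,
                        population=pop,
                        focus=FocusSpec("parameter"),
                        design_space=DesignSpace(IRT_CANDIDATES) if method == "ado" else None,
                        schedule_base=IRT_CANDIDATES.copy() if method == "fixed" else None,
                    )
                )
    return cells


def make_irt_plan(
    reps: int = 1000, n_trials: int = 31, seed: int = 0, condition_sets=None
) -> StudyPlan:
    """Item-response study plan (defaults match the full study: 1000 reps/cell)."""
    return StudyPlan(
        cells=tuple(_irt_cells(condition_sets)),
        reps=reps,
        n_trials=n_trials,
        master_seed=seed,
        name="irt",
    )


_MEMORY_PRIOR_TYPES = ("informative", "misinformative", "uninf_param", "uninf_data")


def _memory_param_prior_for(prior_type: str, pop_name: str) -> Belief:
    b_by_pop = {"memory_high_b": ("beta", 2, 1), "memory_low_b": ("beta", 1, 2)}
    swapped = {"memory_high_b": ("beta", 1, 2), "memory_low_b": ("beta", 2, 1)}
    if prior_type == "informative":
        return memory_param_prior(("beta", 1, 1), b_by_pop[pop_name])
    if prior_type == "misinformative":
        return memory_param_prior(("beta", 1, 1), swapped[pop_name])
    if prior_type == "uninf_param":
        return memory_param_prior(("beta", 1, 1), ("beta", 1, 1))
    if prior_type == "uninf_data":
        return memory_param_prior(("beta", 2, 1), ("beta", 1, 4))
    raise ConfigurationError(f"unknown prior type {prior_type!r}")


def _memory_designs(method: str):
    if method == "ado":
        return DesignSpace(MEMORY_CANDIDATES), None
    return None, np.repeat(MEMORY_FIXED_DELAYS, 10)


def make_memory_param_plan(reps: int = 100, n_trials: int = 100, seed: int = 0) -> StudyPlan:
    """Memory parameter-estimation plan (defaults: 2x2x4x100 = 1600 experiments)."""
    cells = []
    for pop_name in ("memory_high_b", "memory_low_b"):
        pop = make_population(pop_name)
        for prior_type in _MEMORY_PRIOR_TYPES:
            prior = _memory_param_prior_for(prior_type, pop_name)
            for method in ("ado", "fixed"):
                space, sched = _memory_designs(method)
                cells.append(
                    StudyCell(
                        labels={
                            "population": pop_name,
                            "prior": prior_type,
                            "method": method,
                        },
                        method=method,
                        prior=prior,
                        population=pop,
                        focus=FocusSpec("parameter"),
                        design_space=space,
                        schedule_base=sched,
                    )
                )
    return StudyPlan(tuple(cells), reps, n_trials, seed, name="memory_param")


def make_memory_selection_plan(
    reps: int = 100, n_trials: int = 100, seed: int = 0, utility_variant: str = "mi"
) -> StudyPlan:
    """Memory model-selection plan (defaults: 2x2x2x2x100 = 1600 experiments).

    ``utility_variant`` selects the adaptive criterion: ``"mi"`` (model
    focus) or ``"total_entropy"`` (joint focus).
    """
    if utility_variant not in ("mi", "total_entropy"):
        raise ConfigurationError(f"unknown utility variant {utility_variant!r}")
    priors = {
        "priorA": memory_selection_prior(
            [("beta", 1, 1), ("beta", 1, 1)], [("beta", 1, 1), ("beta", 1, 1)]
        ),
        "priorB": memory_selection_prior(
            [("beta", 2, 1), ("beta", 1, 4)], [("beta", 2, 1), ("beta", 1, 80)]
        ),
    }
    cells = []
    for pop_name in ("memory_popA", "memory_popB"):
        pop = make_population(pop_name)
        for prior_label, prior in priors.items():
            informative = (pop_name, prior_label) in (
                ("memory_popA", "priorA"),
                ("memory_popB", "priorB"),
            )
            for gen_model in ("powerlaw", "exponential"):
                for method in ("ado", "fixed"):
                    space, sched = _memory_designs(method)
                    cells.append(
                        StudyCell(
                            labels={
                                "population": pop_name,
                                "prior": prior_label,
                                "prior_status": "informative" if informative else "misinformative",
                                "generating_model": gen_model,
                                "method": method,
                            },
                            method=method,
                            prior=prior,
                            population=pop,
                            focus=FocusSpec("model"),
                            design_space=space,
                            schedule_base=sched,
                            generating_model=gen_model,
                            utility=utility_variant,
                        )
                    )
    return StudyPlan(tuple(cells), reps, n_trials, seed, name="memory_selection")


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Traces of every experiment in a plan, with aggregation helpers."""

    plan: StudyPlan
    traces: list[ExperimentTrace]
    labels: list[dict] = field(default_factory=list)

    def curves(self, by: Sequence[str] | None = None) -> pd.DataFrame:
        """Long-format learning curves grouped by the given label keys.

        Defaults to grouping by every label key present, i.e., one curve per
        cell.  Pooled reporting (e.g., across populations or generating
        models) is obtained by grouping on a subset of keys.
        """
        if not self.traces:
            return pd.DataFrame(
                columns=list(by or []) + ["trial", "mean", "se", "n", "n_excluded"]
            )
        if by is None:
            by = list(self.labels[0])
        groups: dict[tuple, list[ExperimentTrace]] = {}
        for lab, tr in zip(self.labels, self.traces):
            key = tuple(lab.get(k) for k in by)
            groups.setdefault(key, []).append(tr)
        frames = []
        for key, trs in groups.items():
            curve = aggregate_traces(trs)
            df = pd.DataFrame(
                {
                    "trial": curve.trials,
                    "mean": curve.mean,
                    "se": curve.se,
                    "n": curve.n,
                    "n_excluded": curve.n_excluded,
                }
            )
            for k, v in zip(by, key):
                df.insert(0, k, v)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def select(self, **label_values) -> "StudyResult":
        """Sub-result whose traces match all given label values."""
        keep = [
            i
            for i, lab in enumerate(self.labels)
            if all(lab.get(k) == v for k, v in label_values.items())
        ]
        return StudyResult(
            plan=self.plan,
            traces=[self.traces[i] for i in keep],
            labels=[self.labels[i] for i in keep],
        )


def _experiment_rng(master_seed: int, exp_index: int) -> np.random.Generator:
    # Child streams keyed by (master seed, experiment index): any single
    # experiment replays in isolation.
    return np.random.default_rng(np.random.SeedSequence([master_seed, exp_index]))


def run_single(plan: StudyPlan, cell_index: int, rep: int, tables=None) -> ExperimentTrace:
    """Run one (cell, repetition) of a plan; bit-identical on every call."""
    cell = plan.cells[cell_index]
    exp_index = cell_index * plan.reps + rep
    rng = _experiment_rng(plan.master_seed, exp_index)
    truth = sample_ground_truth(cell.population, rng, model=cell.generating_model)
    if cell.method == "fixed":
        design = fixed_schedule(cell.schedule_base, rng)
    else:
        design = cell.design_space
    return run_experiment(
        cell.method,
        cell.prior,
        truth,
        design,
        plan.n_trials,
        rng,
        focus=cell.focus,
        utility=cell.utility,
        digest=plan.digest(),
        seed=exp_index,
        tables=tables,
    )


def run_plan(plan: StudyPlan, progress: bool = False) -> StudyResult:
    """Execute every (cell, repetition) of a plan serially."""
    traces: list[ExperimentTrace] = []
    labels: list[dict] = []
    iterator = enumerate(plan.cells)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(list(iterator), desc=plan.name)
        except ImportError:
            pass
    for ci, cell in iterator:
        cand = (
            cell.design_space.candidates
            if cell.method == "ado"
            else np.unique(cell.schedule_base)
        )
        tables = likelihood_tables(cell.prior, cand)
        for rep in range(plan.reps):
            traces.append(run_single(plan, ci, rep, tables=tables))
            labels.append(dict(cell.labels))
    return StudyResult(plan=plan, traces=traces, labels=labels)


def run_irt_study(plan: StudyPlan | None = None, progress: bool = False) -> StudyResult:
    """Run the item-response parameter-estimation study."""
    plan = plan if plan is not None else make_irt_plan()
    return run_plan(plan, progress=progress)


def run_memory_param_study(plan: StudyPlan | None = None, progress: bool = False) -> StudyResult:
    """Run the memory-retention parameter-estimation study."""
    plan = plan if plan is not None else make_memory_param_plan()
    return run_plan(plan, progress=progress)


def run_memory_model_selection_study(
    plan: StudyPlan | None = None, utility_variant: str = "mi", progress: bool = False
) -> StudyResult:
    """Run the memory-retention model-selection study.

    When no plan is supplied, one is built with the requested utility
    variant (model-focus mutual information or total entropy).
    """
    plan = plan if plan is not None else make_memory_selection_plan(utility_variant=utility_variant)
    return run_plan(plan, progress=progress)


def run_toy_gaussian_demo(
    seed: int = 0,
    n_participants: int = 400,
    prior_mu: tuple = ("normal", 0.0, 1.0),
    population_mu: tuple = ("normal", 0.0, 15.0),
    mu_grid: GridSpec = GridSpec(-40.0, 40.0, 161),
    x0: float = 0.0,
) -> dict:
    """Illustrate prior-misinformation bias with the two-Gaussian toy models.

    Models A and B differ only in response noise (sd 10 vs. 11).  Every
    simulated participant truly responds per Model A, but with locations
    spread more widely than the specified prior anticipates, so single
    responses tend to look more plausible under Model B's (prior-marginal)
    predictive.  Returns the per-model predictive table at the single
    stimulus and summary statistics of the per-participant Bayes factors.
    """
    from .belief import bayes_factor, parse_density
    from .models import make_gaussian_toy_pair

    spec_a, spec_b = make_gaussian_toy_pair()
    belief = population_belief(
        [spec_a, spec_b], [0.5, 0.5], [[prior_mu], [prior_mu]], [mu_grid]
    )
    rng = _experiment_rng(seed, 0)
    pop_dist = parse_density(population_mu)
    log_bfs = []
    for _ in range(n_participants):
        mu_star = float(pop_dist.rvs(random_state=rng))
        y = rng.normal(mu_star, spec_a.constants["sigma"])
        bf = bayes_factor(belief, spec_b.name, spec_a.name, x0, y)
        log_bfs.append(np.log(bf))
    log_bfs = np.array(log_bfs)
    pred = pd.DataFrame(
        {
            "response": belief.response_space,
            "pred_model_A": _model_pred(belief, spec_a.name, x0),
            "pred_model_B": _model_pred(belief, spec_b.name, x0),
        }
    )
    return {
        "predictives": pred,
        "mean_log_bf_B_over_A": float(log_bfs.mean()),
        "frac_favoring_B": float((log_bfs > 0).mean()),
        "n_participants": n_participants,
    }


def _model_pred(belief: Belief, name: str, x0: float) -> np.ndarray:
    from .belief import model_predictive

    return model_predictive(belief, name, x0).probs
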