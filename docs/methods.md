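# Methods

This note records the models, the numerical scheme, and the design choices
behind `adosim`, in enough detail that a reader can judge what the simulation
results do and do not establish.

## Setting

A within-subject adaptive experiment infers a **focus** Φ — a parameter θ
(parameter estimation), a model identity m (model selection), or the joint
state (m, θ) (total entropy) — from binary or real-valued responses y to
chosen stimuli x. Two distributions over states of the world matter:

- the **specified prior** p₁(m, θ): what the experimenter feeds the
  inference engine and, through it, the design criterion;
- the **population prior** p₀(m, θ): the true distribution of traits in the
  participant pool, which governs the data actually observed.

**Prior misinformation** is any gap between the two. The package's central
quantities are the global mutual-information utility U(x) = I(Φ; Y|x)
(computed entirely under p₁), the expected focal divergence U¹(x) (the same
inner divergence, averaged over the population's response distribution
p₀(y|x)), and the exact decomposition of U¹ into response variability
H(Y₀|x), surprisal D_KL(Y₀|x ‖ Y₁|x), and hindsight
E₀[E₁[log p₁(y|x, φ) | y]].

## Likelihood families

| family | p(y = 1 \| x, θ) | parameters | stimulus |
|---|---|---|---|
| item response | .2 + .8 / (1 + e^(−2.72 (θ − x))) | proficiency θ | item difficulty |
| power-law retention | a (x + 1)^(−b) | a, b ∈ [0, 1] | delay (s) |
| exponential retention | a e^(−bx) | a, b ∈ [0, 1] | delay (s) |
| Gaussian toy pair | y ~ N(μ, σ_m), σ_A = 10, σ_B = 11 | location μ | single stimulus |

The item-response constants encode a four-alternative multiple-choice item:
a .2 guessing floor, a .8 range, logistic slope 2.72. The toy pair's 10 and
11 are standard deviations, not variances. Real-valued responses are
discretized onto a finite grid (default: 1601 points spanning ±8 standard
deviations around the pooled mean) so the same discrete machinery serves all
families; rows of every response table are renormalized, so quadrature error
cannot break normalization.

## Discretized inference

Beliefs are finite mixtures: a probability per model and a probability mass
per point of a per-model parameter grid. Three grid styles exist:

- **linspace** — n points including endpoints; default for the unbounded
  proficiency trait: 201 points on [−4, 4], wide enough that populations
  centered at ±2 lose only ~2.3% of their mass to truncation (truncated mass
  above 1% is logged).
- **midpoint** — midpoints of n equal cells of a closed interval; default
  for the retention parameters: a 51 × 51 lattice of cell midpoints on
  [0, 1]², which avoids evaluating Beta densities at endpoints where they
  vanish or diverge.
- **quantile** — points at the prior's quantile midpoints (i + ½)/n, one
  atom per equal slab of prior mass. Used for the model-selection beliefs:
  the exponential model's Beta(1, 80) forgetting-rate prior concentrates
  below b ≈ 0.05, and a uniform 51-cell lattice (first midpoint ≈ 0.0098)
  leaves roughly a third of that prior's draws below half its first cell.
  With a uniform lattice the *informative* prior behaves as misspecified —
  data from small true b look more like the power-law grid — and inference
  about the model identity is poisoned by discretization rather than by the
  phenomenon under study. Quantile grids remove that artifact while leaving
  uniform priors (whose quantile midpoints are the cell midpoints) exactly
  as before.

Updating multiplies joint masses by the likelihood and renormalizes; both
the model marginals and the within-model grids update, and beliefs are
immutable values (each update returns a new belief). A response with zero
marginal probability raises an explicit impossible-observation error. All
logs are natural (everything is in nats); 0·log 0 is treated as 0, and logs
of positive probabilities below 1e-300 are clamped with a warning.

True parameter values are drawn from *continuous* population densities and
are never discretized; only the evaluation metric — the log posterior
probability of the truth — snaps θ\* to the nearest grid point (Euclidean).
This nearest-point convention is our resolution of an otherwise unstated
metric definition.

## Utilities: three independent routes

`global_mi_utility` evaluates the double sum over focal atoms and responses
directly. `utility_kl_form` computes Σ_y D_KL(Φ|y,x ‖ Φ) p₁(y|x) with a
fresh hypothetical Bayes update per candidate response and deliberately
shares no inner loop with the direct route. The entropy identity
I(Φ; Y|x) = H(Y|x) − H(Y|x, Φ) is kept as a third route in the test suite.
Agreement of all three to 1e-10 on randomized beliefs across every family is
enforced by tests, as is the exact (to 1e-10) three-term decomposition of
the expected focal divergence and the Table-style identity U¹ = U when the
population coincides with the belief.

For the experiment loop, the direct double sum is algebraically rearranged
as Σ_φ p(φ) Σ_y p(y|φ)[log p(y|φ) − log p(y)]: the first part depends only
on grid points, not masses, so it is cached per experiment alongside the
per-candidate likelihood tensors. The adaptive policy still rescores every
candidate on every trial, as it must — the belief changes.

## Design policies and studies

Each trial presents exactly one stimulus and collects one response. The
adaptive policy takes the utility argmax over the candidate bank, breaking
exact ties (within 1e-12 nats) in favor of the smallest stimulus, so
selection is deterministic given the belief. The fixed benchmark presents a
pre-committed multiset of stimuli in uniformly random order. Both start from
the same specified prior.

Study conditions:

- **Item response**: 31 candidate difficulties equally spaced on [−3, 3],
  31 trials, both policies restricted to that bank (the fixed design is a
  random permutation of all 31). Condition sets: populations
  {N(0,1), N(−2,1), N(2,1)} under a N(0,1) prior; priors
  {N(2,1), N(0,1), N(0,2)} under a N(2,1) population (uncontrolled
  variation); priors {N(0,1), N(0,.65), N(0,2)} under a N(0,1) population
  (controlled variation). Full plan: 1000 repetitions per cell.
- **Memory, parameter estimation** (power-law model): fixed delays
  {0, 1, 2, 4, 7, 12, 21, 35, 59, 99}, each ten times in random order;
  adaptive bank of all integer delays 0–100; 100 trials. Populations:
  b ~ Beta(2,1) (high forgetting) or Beta(1,2) (low), a ~ Beta(1,1). Priors:
  informative, misinformative (populations swapped), uninformative in
  parameter space (a, b ~ Beta(1,1)), uninformative in data space
  (a ~ Beta(2,1), b ~ Beta(1,4)). Full plan: 2 × 2 × 4 × 100 = 1600
  experiments.
- **Memory, model selection** (power-law vs. exponential, model probability
  ½ each): prior/population A puts a, b ~ Beta(1,1) under both models;
  prior/population B puts a ~ Beta(2,1), b ~ Beta(1,4) under the power-law
  and a ~ Beta(2,1), b ~ Beta(1,80) under the exponential model. The
  generating model is balanced, not randomized. An alternative criterion —
  the total-entropy utility, whose focus is the joint state — is available
  for the same plan. Full plan: 1600 experiments.

Seeding: every experiment's generator derives from
`SeedSequence([master_seed, experiment_index])`, so any single (cell,
repetition) replays bit-exactly in isolation; parallelization would not
change any stream. Learning curves report the per-trial mean and standard
error (sample SD/√n) of the log posterior probability of the true focal
value; −∞ sentinels (zero mass at the truth) are excluded from means with
their count reported, a convention this package chooses explicitly.

## Problem sizes used in the checked replications

The test suite replicates the studies at reduced repetition counts chosen to
keep Monte-Carlo error well below the effect sizes being asserted: 200
repetitions per cell for the item-response study (final-trial adaptive vs.
fixed gaps of ~0.4–1.0 nats against standard errors of ~0.1) and 25
repetitions per cell for the model-selection study (the misinformation dip
is several times ln 2 deep). The decomposition identity is checked on 1000
randomized belief/population/stimulus triples across all families.

## What the synthetic data does and does not emulate

Participants are exchangeable draws from a stationary population; a single
true (m\*, θ\*) governs all of a participant's responses; responses are
conditionally independent across trials. Real adaptive experiments violate
these in known ways — parameter drift, practice and fatigue effects,
response dependencies, and misspecification of the likelihood family
itself (the true state then has zero prior mass, a regime this package does
not simulate). Passing tests therefore establish the internal behavior of
the design criterion under prior misinformation, not robustness of adaptive
designs to structural model error.

## Known limitations

- Inference is grid-based only; no particle or MCMC posterior
  representation, so very concentrated posteriors are limited by grid
  resolution. One visible consequence: after 31 item-response trials the
  posterior standard deviation (~0.16) spans ~4 cells of the 201-point
  grid, so the posterior *mode* rarely lands exactly on the grid point
  nearest θ\* even when the estimate is accurate by any interval criterion.
- The adaptive policy is greedy one-step mutual information; no
  exploration bonus (e.g., upper-confidence-bound variants) is implemented,
  though the policy accepts pluggable utility callables.
- Hierarchical pooling of information across participants is out of scope;
  every participant is analyzed with the same specified prior.
- The toy Gaussian demonstration is qualitative and configurable; its prior
  and population spreads are illustrative defaults, not estimates.
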