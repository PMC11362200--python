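"""Tests for the mutual-information utilities: values, cross-route agreement,
and information-theoretic invariants."""

import numpy as np
import pytest
from scipy.special import xlogy

from adosim import (
    ConfigurationError,
    FocusSpec,
    ParamGrid,
    global_mi_utility,
    make_belief,
    make_powerlaw_model,
    mi_scores,
    model_predictive,
    prior_predictive,
    response_entropy,
    total_entropy_utility,
    utility_curve,
    utility_kl_form,
)
from conftest import random_belief, random_stimulus

PARAM = FocusSpec("parameter")
MODEL = FocusSpec("model")
JOINT = FocusSpec("joint")


def deterministic_opposite_belief():
    # two equal-mass parameter atoms predicting recall with certainty vs. never
    grid = ParamGrid(np.array([[1.0, 0.0], [0.0, 0.0]]), np.array([0.5, 0.5]))
    return make_belief([make_powerlaw_model()], [1.0], [grid])


def entropy_route(belief, x, focus):
    """Third, independent route: I(Phi; Y|x) = H(Y|x) - H(Y|x, Phi)."""
    h_y = response_entropy(prior_predictive(belief, x))
    if focus.kind == "model":
        h_cond = sum(
            pm * response_entropy(model_predictive(belief, nm, x))
            for pm, nm in zip(belief.model_probs, belief.model_names)
        )
        return h_y - h_cond
    h_cond = 0.0
    for pm, ms, grid in zip(belief.model_probs, belief.model_specs, belief.param_grids):
        table = ms.prob_table(x, grid.points)
        h_cond += pm * float(grid.masses @ (-xlogy(table, table).sum(axis=1)))
    return h_y - h_cond


class TestGlobalUtility:
    def test_degenerate_focus_prior_is_zero(self):
        point = ParamGrid(np.array([[0.7, 0.2]]), np.array([1.0]))
        b = make_belief([make_powerlaw_model()], [1.0], [point])
        assert global_mi_utility(b, 5.0, PARAM).value == pytest.approx(0.0, abs=1e-12)
        assert global_mi_utility(b, 5.0, MODEL).value == pytest.approx(0.0, abs=1e-12)

    def test_opposite_deterministic_predictions_give_ln2(self):
        b = deterministic_opposite_belief()
        assert global_mi_utility(b, 3.0, PARAM).value == pytest.approx(np.log(2), abs=1e-12)
        assert utility_kl_form(b, 3.0, PARAM).value == pytest.approx(np.log(2), abs=1e-12)

    @pytest.mark.parametrize("family", ["irt", "powerlaw", "memory_pair", "gaussian_toy"])
    def test_three_routes_agree_on_random_beliefs(self, family, rng):
        for _ in range(8):
            b = random_belief(rng, family)
            x = random_stimulus(rng, family)
            foci = [JOINT] if not b.single_model else [PARAM]
            if not b.single_model:
                foci.append(MODEL)
            for focus in foci:
                direct = global_mi_utility(b, x, focus).value
                kl = utility_kl_form(b, x, focus).value
                ent = entropy_route(b, x, focus)
                assert kl == pytest.approx(direct, abs=1e-10)
                assert ent == pytest.approx(direct, abs=1e-10)
                assert direct >= -1e-10

    def test_parameter_focus_needs_single_model(self, rng):
        b = random_belief(rng, "memory_pair")
        with pytest.raises(ConfigurationError):
            global_mi_utility(b, 1.0, PARAM)

    def test_x_independent_likelihood_gives_flat_curve(self):
        # b = 0 atoms: recall probability equals a at every delay
        grid = ParamGrid(np.array([[0.3, 0.0], [0.9, 0.0]]), np.array([0.4, 0.6]))
        b = make_belief([make_powerlaw_model()], [1.0], [grid])
        curve = utility_curve(b, np.arange(0, 101, 10), PARAM)
        np.testing.assert_allclose(curve["utility"], curve["utility"].iloc[0], atol=1e-12)

    def test_invariant_to_atom_permutation(self, rng):
        b = random_belief(rng, "powerlaw")
        perm = rng.permutation(b.param_grids[0].n_atoms)
        g = b.param_grids[0]
        b2 = make_belief(
            b.model_specs, b.model_probs, [ParamGrid(g.points[perm], g.masses[perm])]
        )
        x = 17.0
        assert global_mi_utility(b2, x, PARAM).value == pytest.approx(
            global_mi_utility(b, x, PARAM).value, abs=1e-12
        )


class TestTotalEntropy:
    def test_single_atom_is_zero(self):
        point = ParamGrid(np.array([[0.7, 0.2]]), np.array([1.0]))
        b = make_belief([make_powerlaw_model()], [1.0], [point])
        assert total_entropy_utility(b, 4.0).value == pytest.approx(0.0, abs=1e-12)

    def test_single_model_reduces_to_parameter_focus(self, rng):
        b = random_belief(rng, "exponential")
        x = random_stimulus(rng, "exponential")
        assert total_entropy_utility(b, x).value == pytest.approx(
            global_mi_utility(b, x, PARAM).value, abs=1e-12
        )

    def test_joint_dominates_model_focus(self, rng):
        # chain rule: I((M, Theta); Y) >= I(M; Y)
        for _ in range(10):
            b = random_belief(rng, "memory_pair")
            x = random_stimulus(rng, "memory_pair")
            assert total_entropy_utility(b, x).value >= (
                global_mi_utility(b, x, MODEL).value - 1e-10
            )


def mi_from_joint(joint):
    """Independent MI from an explicit joint p(phi, y) table."""
    pphi = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    return float(xlogy(joint, joint).sum() - xlogy(joint, pphi * py).sum())


class TestDataProcessing:
    def test_coarsening_responses_never_increases_utility(self, rng):
        b = random_belief(rng, "gaussian_toy")
        x = 0.0
        # explicit joint over (atoms, responses)
        blocks = []
        for pm, ms, g in zip(b.model_probs, b.model_specs, b.param_grids):
            blocks.append(pm * g.masses[:, np.newaxis] * ms.prob_table(x, g.points))
        joint = np.concatenate(blocks, axis=0)
        full = mi_from_joint(joint)
        assert full == pytest.approx(total_entropy_utility(b, x).value, abs=1e-10)
        # merge adjacent response bins pairwise
        y_dim = joint.shape[1] - joint.shape[1] % 2
        merged = joint[:, :y_dim].reshape(joint.shape[0], -1, 2).sum(axis=2)
        merged = np.concatenate([merged, joint[:, y_dim:]], axis=1)
        assert mi_from_joint(merged) <= full + 1e-10


class TestVectorizedScores:
    def test_batch_matches_scalar_calls(self, rng):
        b = random_belief(rng, "memory_pair")
        xs = np.array([0.0, 5.0, 40.0, 100.0])
        batch = mi_scores(b, xs, MODEL)
        singles = [global_mi_utility(b, x, MODEL).value for x in xs]
        np.testing.assert_allclose(batch, singles, atol=1e-12)
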