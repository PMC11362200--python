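"""Unit and property tests for the discretized belief engine."""

import numpy as np
import pytest

from adosim import (
    DomainError,
    GridSpec,
    ImpossibleObservationError,
    ParamGrid,
    bayes_factor,
    bayes_update,
    belief_from_frame,
    belief_to_frame,
    discretize_joint,
    discretize_prior,
    log_posterior_of_truth,
    make_belief,
    make_powerlaw_model,
    model_predictive,
    prior_predictive,
    FocusSpec,
    GroundTruth,
)
from conftest import random_belief, random_stimulus


def two_atom_belief(p_low=0.2, p_high=0.8, masses=(0.5, 0.5)):
    # power-law atoms with b = 0 give delay-independent recall probability a
    grid = ParamGrid(np.array([[p_low, 0.0], [p_high, 0.0]]), np.array(masses))
    return make_belief([make_powerlaw_model()], [1.0], [grid])


class TestDiscretization:
    def test_uniform_density_gives_equal_masses(self):
        grid = discretize_prior(("beta", 1, 1), GridSpec(0, 1, 11, "midpoint"))
        np.testing.assert_allclose(grid.masses, 1 / 11, atol=1e-15)
        assert np.all((grid.points > 0) & (grid.points < 1))

    def test_normal_symmetry(self):
        grid = discretize_prior(("normal", 0, 1), GridSpec(-4, 4, 201))
        np.testing.assert_allclose(grid.masses, grid.masses[::-1], atol=1e-12)
        assert grid.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_snaps_to_grid(self):
        grid = discretize_prior(("point", 0.5), GridSpec(0, 1, 11, "linspace"))
        assert grid.masses[5] == 1.0
        assert grid.masses.sum() == 1.0

    def test_zero_mass_on_grid_raises(self):
        with pytest.raises(DomainError):
            discretize_prior(("uniform", 5, 6), GridSpec(0, 1, 11, "midpoint"))

    def test_quantile_style_has_uniform_masses(self):
        grid = discretize_prior(("beta", 1, 80), GridSpec(0, 1, 51, "quantile"))
        np.testing.assert_allclose(grid.masses, 1 / 51, atol=1e-15)
        # the grid actually resolves the concentrated prior
        assert grid.points[0, 0] < 1e-3 and grid.points[-1, 0] < 0.1

    def test_joint_product_grid(self):
        grid = discretize_joint(
            [("beta", 1, 1), ("beta", 2, 1)],
            [GridSpec(0, 1, 5, "midpoint"), GridSpec(0, 1, 7, "midpoint")],
        )
        assert grid.points.shape == (35, 2)
        assert grid.masses.sum() == pytest.approx(1.0, abs=1e-12)


class TestPredictives:
    def test_single_atom_equals_likelihood(self):
        b = two_atom_belief(masses=(1.0, 0.0))
        pred = prior_predictive(b, 13.0)
        assert pred.prob_of(1) == pytest.approx(0.2, abs=1e-15)

    def test_two_equal_atoms_average(self):
        pred = prior_predictive(two_atom_belief(), 7.0)
        assert pred.prob_of(1) == pytest.approx(0.5, abs=1e-14)

    def test_model_predictive_hand_average(self):
        grid = ParamGrid(np.array([[0.4, 0.3], [0.6, 0.3]]), np.array([0.5, 0.5]))
        b = make_belief([make_powerlaw_model()], [1.0], [grid])
        assert model_predictive(b, "powerlaw", 0.0).prob_of(1) == pytest.approx(0.5, abs=1e-14)

    def test_mixture_law_of_total_probability(self, rng):
        for _ in range(10):
            b = random_belief(rng, "memory_pair")
            x = random_stimulus(rng, "memory_pair")
            mixed = sum(
                pm * model_predictive(b, name, x).probs
                for pm, name in zip(b.model_probs, b.model_names)
            )
            np.testing.assert_allclose(mixed, prior_predictive(b, x).probs, atol=1e-12)

    def test_predictive_normalized_on_random_beliefs(self, rng):
        for family in ("irt", "gaussian_toy"):
            b = random_belief(rng, family)
            assert prior_predictive(b, random_stimulus(rng, family)).probs.sum() == pytest.approx(
                1.0, abs=1e-10
            )


class TestBayesUpdate:
    def test_hand_bayes_rule(self):
        b = two_atom_belief()
        post = bayes_update(b, 3.0, 1)
        np.testing.assert_allclose(post.param_grids[0].masses, [0.2, 0.8], atol=1e-14)
        # input belief unmodified
        np.testing.assert_allclose(b.param_grids[0].masses, [0.5, 0.5])

    def test_constant_likelihood_leaves_belief_unchanged(self):
        b = two_atom_belief(0.5, 0.5)
        post = bayes_update(b, 9.0, 1)
        np.testing.assert_allclose(post.param_grids[0].masses, b.param_grids[0].masses, atol=1e-12)

    def test_zero_likelihood_atom_gets_zero_mass(self):
        b = two_atom_belief(0.0, 0.8)
        post = bayes_update(b, 2.0, 1)
        assert post.param_grids[0].masses[0] == 0.0

    def test_impossible_observation_raises(self):
        b = two_atom_belief(1.0, 1.0)
        with pytest.raises(ImpossibleObservationError):
            bayes_update(b, 2.0, 0)

    def test_update_order_and_batch_consistency(self, rng):
        for family in ("irt", "memory_pair"):
            b = random_belief(rng, family)
            obs = [(random_stimulus(rng, family), int(rng.integers(2))) for _ in range(2)]
            seq12 = bayes_update(bayes_update(b, *obs[0]), *obs[1])
            seq21 = bayes_update(bayes_update(b, *obs[1]), *obs[0])
            for g1, g2 in zip(seq12.param_grids, seq21.param_grids):
                np.testing.assert_allclose(g1.masses, g2.masses, atol=1e-10)
            np.testing.assert_allclose(seq12.model_probs, seq21.model_probs, atol=1e-10)

    def test_posterior_model_probs_track_model_predictive(self, rng):
        for _ in range(10):
            b = random_belief(rng, "memory_pair")
            x = random_stimulus(rng, "memory_pair")
            y = int(rng.integers(2))
            expected = np.array(
                [pm * model_predictive(b, nm, x).prob_of(y)
                 for pm, nm in zip(b.model_probs, b.model_names)]
            )
            post = bayes_update(b, x, y)
            np.testing.assert_allclose(post.model_probs, expected / expected.sum(), atol=1e-12)


class TestBayesFactor:
    def test_identical_models_give_unity(self, rng):
        g = ParamGrid(rng.random((5, 2)), np.full(5, 0.2))
        b = make_belief(
            [make_powerlaw_model("m1"), make_powerlaw_model("m2")], [0.5, 0.5], [g, g]
        )
        assert bayes_factor(b, "m1", "m2", 4.0, 1) == pytest.approx(1.0, abs=1e-14)

    def test_reciprocity(self, rng):
        b = random_belief(rng, "memory_pair")
        m1, m2 = b.model_names
        prod = bayes_factor(b, m1, m2, 5.0, 1) * bayes_factor(b, m2, m1, 5.0, 1)
        assert prod == pytest.approx(1.0, abs=1e-12)

    def test_single_atom_grids_give_pointwise_ratio(self):
        g1 = ParamGrid(np.array([[0.8, 0.0]]), np.array([1.0]))
        g2 = ParamGrid(np.array([[0.4, 0.0]]), np.array([1.0]))
        b = make_belief(
            [make_powerlaw_model("m1"), make_powerlaw_model("m2")], [0.5, 0.5], [g1, g2]
        )
        assert bayes_factor(b, "m1", "m2", 0.0, 1) == pytest.approx(2.0, abs=1e-12)


class TestLogPosteriorOfTruth:
    def test_model_focus(self):
        g = ParamGrid(np.array([[0.5, 0.5]]), np.array([1.0]))
        b = make_belief(
            [make_powerlaw_model("m1"), make_powerlaw_model("m2")], [0.5, 0.5], [g, g]
        )
        truth = GroundTruth(b.model_specs[0], np.array([0.5, 0.5]))
        assert log_posterior_of_truth(b, truth, FocusSpec("model")) == pytest.approx(
            np.log(0.5), abs=1e-14
        )

    def test_point_mass_at_truth_gives_zero(self):
        b = two_atom_belief(masses=(1.0, 0.0))
        truth = GroundTruth(b.model_specs[0], np.array([0.2, 0.0]))
        assert log_posterior_of_truth(b, truth, FocusSpec("parameter")) == 0.0

    def test_zero_mass_returns_neg_infinity_not_error(self):
        b = two_atom_belief(masses=(0.0, 1.0))
        truth = GroundTruth(b.model_specs[0], np.array([0.2, 0.0]))
        assert log_posterior_of_truth(b, truth, FocusSpec("parameter")) == -np.inf

    def test_confirming_observation_is_nondecreasing(self):
        b = two_atom_belief(1.0, 0.0)  # atom 0 always recalls, atom 1 never
        truth = GroundTruth(b.model_specs[0], np.array([1.0, 0.0]))
        before = log_posterior_of_truth(b, truth, FocusSpec("parameter"))
        after = log_posterior_of_truth(
            bayes_update(b, 5.0, 1), truth, FocusSpec("parameter")
        )
        assert after >= before


class TestSerialization:
    def test_frame_round_trip(self, rng):
        b = random_belief(rng, "memory_pair")
        frame = belief_to_frame(b)
        assert frame["mass"].sum() == pytest.approx(1.0, abs=1e-12)
        b2 = belief_from_frame(frame, b.model_specs)
        np.testing.assert_allclose(b2.model_probs, b.model_probs, atol=1e-12)
        for g1, g2 in zip(b.param_grids, b2.param_grids):
            np.testing.assert_allclose(g1.masses, g2.masses, atol=1e-12)
            np.testing.assert_allclose(g1.points, g2.points)
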