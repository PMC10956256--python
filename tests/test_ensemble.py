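"""Unit and property tests for the DE-PSO ensemble weight optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elpgv.ensemble import (
    DEGENERATE_FITNESS,
    BasePredictionSet,
    DegenerateFitnessError,
    SwarmConfig,
    SwarmState,
    crossover,
    de_mutation,
    ensemble_predict,
    fitness,
    greedy_select,
    initialize_swarm,
    select_reference_method,
    train_elpgv,
    train_weights_once,
    update_velocity,
)

from conftest import FixedRng, grid_search_best_fitness, toy_two_method_problem


def _pset(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"m{j}" for j in range(values.shape[1])]
    ids = np.array([f"i{i}" for i in range(values.shape[0])])
    return BasePredictionSet(ids, names, values)


class TestEnsemblePredict:
    def test_identity_weight_selects_column(self):
        rng = np.random.default_rng(0)
        preds = _pset(rng.normal(size=(10, 4)))
        out = ensemble_predict([1, 0, 0, 0], preds)
        np.testing.assert_array_equal(out, preds.values[:, 0])

    def test_direct_arithmetic(self):
        preds = _pset(np.array([[1.0, 3.0], [2.0, 4.0]]))
        np.testing.assert_allclose(ensemble_predict([0.5, 0.5], preds), [2.0, 3.0])

    def test_zero_weights_give_zero_vector(self):
        preds = _pset(np.random.default_rng(1).normal(size=(6, 2)))
        np.testing.assert_array_equal(ensemble_predict([0, 0], preds), np.zeros(6))

    def test_dimension_mismatch_rejected(self):
        preds = _pset(np.ones((5, 3)))
        with pytest.raises(ValueError, match="3 methods"):
            ensemble_predict([0.5, 0.5], preds)


class TestFitness:
    def test_affine_invariance_gives_one(self):
        t = np.array([0.3, -1.2, 2.0, 0.7])
        preds = _pset((2.0 * t + 5.0)[:, None].repeat(2, axis=1))
        assert fitness([0.5, 0.5], preds, t) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        t = np.array([1.0, 2.0, 4.0])
        preds = _pset(np.column_stack([-t, -t]))
        assert fitness([1.0, 0.0], preds, t) == pytest.approx(-1.0)

    def test_hand_computed_zero_correlation(self):
        # ensemble (3, 2, 3) vs target (1, 2, 3): centered dot product is 0
        preds = _pset(np.array([[1.0, 2.0], [1.0, 1.0], [2.0, 1.0]]))
        target = [1.0, 2.0, 3.0]
        assert fitness([1.0, 1.0], preds, target) == pytest.approx(0.0, abs=1e-12)
        # cross-check with an independent correlation routine
        from scipy.stats import pearsonr

        assert pearsonr(ensemble_predict([1, 1], preds), target).statistic == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_degenerate_output_yields_sentinel_not_zero(self):
        preds = _pset(np.random.default_rng(2).normal(size=(5, 2)))
        assert fitness([0.0, 0.0], preds, np.arange(5.0)) == DEGENERATE_FITNESS

    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_scale_free_in_weights(self, c, seed):
        rng = np.random.default_rng(seed)
        preds = _pset(rng.normal(size=(12, 3)))
        t = rng.normal(size=12)
        w = rng.uniform(0.05, 1.0, 3)
        assert fitness(c * w, preds, t) == pytest.approx(fitness(w, preds, t))


class TestSelectReferenceMethod:
    def test_singleton(self):
        preds = _pset(np.arange(4.0)[:, None] + 1, ["only"])
        assert select_reference_method(preds, [1.0, 2.0, 3.0, 5.0]) == "only"

    def test_exact_fit_dominates_noise(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        noise = np.array([0.3, -1.0, 0.2, 0.1])
        preds = _pset(np.column_stack([y, noise]), ["exact", "noise"])
        assert select_reference_method(preds, y) == "exact"

    def test_hand_computed_pearson_ordering(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        A = np.array([1.0, 2.0, 2.0, 4.0])   # r > 0
        B = np.array([4.0, 3.0, 2.0, 1.0])   # r = -1
        preds = _pset(np.column_stack([A, B]), ["A", "B"])
        assert select_reference_method(preds, y) == "A"

    def test_tie_breaks_by_method_order(self):
        y = np.array([1.0, 2.0, 3.0])
        preds = _pset(np.column_stack([y, y]), ["first", "second"])
        assert select_reference_method(preds, y) == "first"

    def test_all_degenerate_is_error(self):
        preds = _pset(np.ones((4, 2)), ["a", "b"])
        with pytest.raises(DegenerateFitnessError):
            select_reference_method(preds, np.arange(4.0))


class TestInitializeSwarm:
    def test_degenerate_interval_pins_weights(self):
        preds, target = toy_two_method_problem(0)
        cfg = SwarmConfig(w_min=0.5, w_max=0.5)
        state = initialize_swarm(cfg, preds, target, np.random.default_rng(0))
        np.testing.assert_array_equal(state.weights, np.full((20, 2), 0.5))

    def test_default_config_bounds_and_size(self):
        preds, target = toy_two_method_problem(1)
        state = initialize_swarm(SwarmConfig(), preds, target, np.random.default_rng(1))
        assert state.weights.shape == (20, 2)
        assert state.weights.min() >= 0.0 and state.weights.max() <= 1.0
        assert state.velocities.min() >= -0.01 and state.velocities.max() <= 0.01
        best = int(np.argmax(state.fitness))
        assert state.incumbent_fitness == state.fitness[best]
        np.testing.assert_array_equal(state.incumbent, state.weights[best])

    def test_same_seed_is_bit_identical(self):
        preds, target = toy_two_method_problem(2)
        s1 = initialize_swarm(SwarmConfig(), preds, target, np.random.default_rng(9))
        s2 = initialize_swarm(SwarmConfig(), preds, target, np.random.default_rng(9))
        np.testing.assert_array_equal(s1.weights, s2.weights)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError, match="4 particles"):
            SwarmConfig(m=3)


def _state_for_mutation():
    weights = np.array([[0.3, 0.3], [0.4, 0.6], [0.8, 0.2], [0.2, 0.6]])
    velocities = np.zeros((4, 2))
    velocities[0] = [0.01, -0.01]
    return SwarmState(
        weights=weights, velocities=velocities,
        fitness=np.zeros(4), incumbent=weights[0].copy(),
        incumbent_fitness=0.0,
    )


class TestDeMutation:
    def test_worked_difference_vector(self):
        state = _state_for_mutation()
        rng = FixedRng(choices=[[1, 2, 3]])
        P, H = de_mutation(state, 0, SwarmConfig(m=4), rng)
        np.testing.assert_allclose(H, [0.7, 0.4])   # W1 + 0.5*(W2 - W3)
        np.testing.assert_allclose(P, [0.31, 0.29])  # W0 + V0

    def test_clamping_to_weight_box(self):
        state = _state_for_mutation()
        state.weights[1] = [0.9, 0.1]
        state.weights[2] = [1.0, 1.0]
        state.weights[3] = [0.0, 0.0]
        rng = FixedRng(choices=[[1, 2, 3]])
        _, H = de_mutation(state, 0, SwarmConfig(m=4), rng)
        np.testing.assert_allclose(H, [1.0, 0.6])    # raw (1.4, 0.6) clamped

    def test_indices_exclude_self_and_are_distinct(self):
        state = _state_for_mutation()
        cfg = SwarmConfig(m=4)
        rng = np.random.default_rng(3)
        for _ in range(50):
            de_mutation(state, 0, cfg, rng)  # only checks it never raises
        # distinctness is enforced by choice(..., replace=False) over peers


class TestCrossover:
    def test_takes_mutant_below_cr(self):
        H, W = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        out = crossover(H, W, SwarmConfig(cr=0.3), FixedRng(uniforms=[0.2]))
        np.testing.assert_array_equal(out, H)

    def test_keeps_previous_above_cr(self):
        H, W = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        out = crossover(H, W, SwarmConfig(cr=0.3), FixedRng(uniforms=[0.9]))
        np.testing.assert_array_equal(out, W)

    def test_cr_one_always_takes_mutant(self):
        H, W = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        for u in (0.0, 0.5, 1.0):
            out = crossover(H, W, SwarmConfig(cr=1.0), FixedRng(uniforms=[u]))
            np.testing.assert_array_equal(out, H)


class TestGreedySelect:
    U, P, W = np.array([1.0]), np.array([2.0]), np.array([3.0])

    def test_best_candidate_wins(self):
        w, f = greedy_select(self.U, self.P, self.W, 0.9, 0.5, 0.7)
        np.testing.assert_array_equal(w, self.U)
        assert f == 0.9

    def test_previous_weights_survive_poor_candidates(self):
        w, f = greedy_select(self.U, self.P, self.W, 0.1, 0.2, 0.7)
        np.testing.assert_array_equal(w, self.W)
        assert f == 0.7

    def test_ties_favor_newest_candidate(self):
        w, _ = greedy_select(self.U, self.P, self.W, 0.5, 0.5, 0.5)
        np.testing.assert_array_equal(w, self.U)


class TestUpdateVelocity:
    def test_fixed_point(self):
        v = update_velocity(
            np.zeros(2), np.full(2, 0.5), np.full(2, 0.5), np.full(2, 0.5),
            SwarmConfig(), FixedRng(uniforms=[[0.5, 0.5]]),
        )
        np.testing.assert_array_equal(v, np.zeros(2))

    def test_direct_arithmetic(self):
        W_prev = np.array([0.5, 0.5])
        W_new = W_prev + np.array([0.004, -0.004])
        v = update_velocity(
            np.array([0.001, 0.001]), W_new, W_prev, W_prev,
            SwarmConfig(), FixedRng(uniforms=[[0.5, 0.5]]),
        )
        np.testing.assert_allclose(v, [0.005, -0.003])

    def test_clamped_to_velocity_box(self):
        v = update_velocity(
            np.array([0.5, -0.5]), np.zeros(2), np.zeros(2), np.zeros(2),
            SwarmConfig(), FixedRng(uniforms=[[0.0, 0.0]]),
        )
        np.testing.assert_allclose(v, [0.01, -0.01])


class TestTrainWeightsOnce:
    def test_reaches_perfect_fitness_when_target_is_a_column(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=30)
        preds = _pset(np.column_stack([t, rng.normal(size=30)]))
        _, best, _ = train_weights_once(preds, t, SwarmConfig(), np.random.default_rng(6))
        assert best == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_oracle_on_toy_problem(self):
        preds, target = toy_two_method_problem(11)
        oracle = grid_search_best_fitness(preds, target)
        _, best, _ = train_weights_once(
            preds, target, SwarmConfig(), np.random.default_rng(11)
        )
        assert best >= oracle - 1e-3

    def test_same_seed_identical_weights(self):
        preds, target = toy_two_method_problem(7)
        w1, f1, t1 = train_weights_once(preds, target, SwarmConfig(), np.random.default_rng(3))
        w2, f2, t2 = train_weights_once(preds, target, SwarmConfig(), np.random.default_rng(3))
        np.testing.assert_array_equal(w1, w2)
        assert f1 == f2
        np.testing.assert_array_equal(t1, t2)

    def test_trajectory_non_decreasing_and_weights_bounded(self):
        preds, target = toy_two_method_problem(8)
        w, _, traj = train_weights_once(preds, target, SwarmConfig(), np.random.default_rng(8))
        assert np.all(np.diff(traj) >= 0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_constant_target_aborts(self):
        preds, _ = toy_two_method_problem(9)
        with pytest.raises(DegenerateFitnessError):
            train_weights_once(preds, np.ones(20), SwarmConfig(), np.random.default_rng(0))


class TestTrainElpgv:
    def test_single_repeat_equals_one_run(self, four_method_predictions):
        preds, g = four_method_predictions
        cfg = SwarmConfig(repeats=1, seed=17)
        model = train_elpgv(preds, cfg, phenotypes=g)
        w, _, _ = train_weights_once(preds, g, cfg, np.random.default_rng(17))
        np.testing.assert_array_equal(model.averaged_weights, w)

    def test_averaged_weights_are_mean_of_repeats(self, four_method_predictions):
        preds, g = four_method_predictions
        model = train_elpgv(preds, SwarmConfig(repeats=10, seed=1), phenotypes=g)
        np.testing.assert_allclose(
            model.averaged_weights, model.per_repeat_weights.mean(axis=0)
        )
        assert model.per_repeat_weights.shape == (10, 4)
        # repeats genuinely differ (distinct per-repeat seeds)
        assert np.ptp(model.per_repeat_weights, axis=0).max() > 0

    def test_reference_mode_targets_reference_column(self, four_method_predictions):
        preds, _ = four_method_predictions
        model = train_elpgv(
            preds, SwarmConfig(repeats=5, seed=2), reference_method="BayesB"
        )
        assert model.mode == "reference"
        assert model.reference_method == "BayesB"
        # reference weight should dominate on average: correlating with its
        # own column rewards mass on that column
        j = preds.method_names.index("BayesB")
        assert model.averaged_weights[j] == max(model.averaged_weights)

    def test_mode_argument_validation(self, four_method_predictions):
        preds, g = four_method_predictions
        with pytest.raises(ValueError, match="exactly one"):
            train_elpgv(preds, SwarmConfig(repeats=1))
        with pytest.raises(ValueError, match="exactly one"):
            train_elpgv(preds, SwarmConfig(repeats=1), phenotypes=g,
                        reference_method="BayesA")
        with pytest.raises(ValueError, match="unknown reference"):
            train_elpgv(preds, SwarmConfig(repeats=1), reference_method="nope")

    def test_end_to_end_determinism(self, four_method_predictions):
        preds, g = four_method_predictions
        cfg = SwarmConfig(repeats=8, seed=21)
        m1 = train_elpgv(preds, cfg, phenotypes=g)
        m2 = train_elpgv(preds, cfg, phenotypes=g)
        np.testing.assert_array_equal(m1.per_repeat_weights, m2.per_repeat_weights)
        np.testing.assert_array_equal(m1.fitness_trajectories, m2.fitness_trajectories)
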