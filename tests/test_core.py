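"""Unit and property tests for the per-step mathematics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hpcoevo as h
from hpcoevo.exceptions import ParameterError, ReplicatorStagnationWarning

from .conftest import random_valid_params, random_valid_state
from .oracle import oracle_step


class TestInterpolateTypeValues:
    @pytest.mark.parametrize(
        "v1, vn, n, index, expected",
        [
            (1.0, 10.0, 10, 5, 5.0),  # midpoint of a 1..10 ramp over ten types
            (3.0, 1.5, 4, 2, 2.5),
            (3.0, 1.5, 4, 3, 2.0),
        ],
    )
    def test_linear_form(self, v1, vn, n, index, expected):
        values = h.interpolate_type_values(v1, vn, n)
        assert values[index - 1] == pytest.approx(expected, abs=1e-12)

    def test_endpoints_exact(self):
        values = h.interpolate_type_values(3.0, 1.5, 4)
        assert values[0] == 3.0 and values[-1] == 1.5
        np.testing.assert_allclose(values, [3.0, 2.5, 2.0, 1.5], atol=1e-12)

    @pytest.mark.parametrize("c,n", [(0.0, 2), (7.5, 9)])
    def test_constant_endpoints(self, c, n):
        np.testing.assert_array_equal(h.interpolate_type_values(c, c, n), np.full(n, c))

    @pytest.mark.parametrize("n", [1, 0, -3])
    def test_rejects_too_few_types(self, n):
        with pytest.raises(ParameterError):
            h.interpolate_type_values(1.0, 2.0, n)


class TestAggregateUtilities:
    def test_empty_population_gives_zero_cross_utility(self, full_params):
        state = h.initial_state(replace(full_params, initial_population_humans=0.0))
        u_hp, _, _, _ = h.aggregate_utilities(state, replace(full_params, initial_population_humans=0.0))
        assert u_hp == 0.0

    def test_hand_evaluated_two_type_case(self):
        params = h.HPCParams(
            number_types_humans=2,
            utility_per_capita_type_1_humans_to_plants=0.0,
            utility_per_capita_type_n_humans_to_plants=2.0,
            initial_population_humans=10.0,
        )
        state = h.initial_state(params, type_proportions_humans=[0.5, 0.5])
        u_hp, _, _, _ = h.aggregate_utilities(state, params)
        assert u_hp == pytest.approx(10.0, abs=1e-12)

    def test_degenerate_distribution_recovers_endpoint(self, full_params):
        state = h.initial_state(full_params)  # all mass on type 1
        _, _, u_bh, u_bp = h.aggregate_utilities(state, full_params)
        assert u_bh == pytest.approx(full_params.utility_other_to_type_1_humans, abs=1e-12)
        assert u_bp == pytest.approx(full_params.utility_other_to_type_1_plants, abs=1e-12)


class TestCarryingCapacities:
    def test_cap_binding(self):
        assert h.carrying_capacities(5, 10, 7, 100, 50) == (15, 50)

    def test_zero_utilities(self):
        assert h.carrying_capacities(0, 0, 0, 0, 123.0) == (0, 0)

    def test_infinite_area_never_binds(self):
        _, k_p = h.carrying_capacities(1, 2, 7, 100, math.inf)
        assert k_p == 107


class TestLogisticUpdate:
    def test_fixed_point_at_capacity(self):
        assert h.logistic_update(100.0, 0.3, 100.0) == pytest.approx(100.0)

    def test_hand_evaluated(self):
        assert h.logistic_update(50.0, 0.1, 100.0) == pytest.approx(52.5, abs=1e-12)

    def test_zero_growth_rate(self):
        assert h.logistic_update(42.0, 0.0, 7.0) == 42.0

    def test_zero_capacity_decays(self):
        assert h.logistic_update(10.0, 0.25, 0.0) == pytest.approx(7.5)
        assert h.logistic_update(10.0, 1.0, 0.0) == 0.0

    @pytest.mark.parametrize("pop,r,k", [(-1, 0.1, 10), (1, -0.1, 10), (1, 0.1, -10)])
    def test_rejects_negative_inputs(self, pop, r, k):
        with pytest.raises(ParameterError):
            h.logistic_update(pop, r, k)


class TestUndirectedVariation:
    def test_zero_level_is_identity(self):
        pop = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(h.undirected_variation(pop, 0.0), pop)

    def test_uniform_is_fixed_point(self):
        pop = np.full(4, 0.25)
        np.testing.assert_allclose(h.undirected_variation(pop, 0.7), pop, atol=1e-15)

    def test_hand_evaluated(self):
        np.testing.assert_allclose(
            h.undirected_variation(np.array([1.0, 0.0]), 0.5), [0.75, 0.25], atol=1e-15
        )

    def test_full_level_yields_uniform(self):
        out = h.undirected_variation(np.array([0.9, 0.1, 0.0]), 1.0)
        np.testing.assert_allclose(out, np.full(3, 1 / 3), atol=1e-15)

    @pytest.mark.parametrize("v", [-0.1, 1.1])
    def test_rejects_out_of_range_level(self, v):
        with pytest.raises(ParameterError):
            h.undirected_variation(np.array([0.5, 0.5]), v)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        st.floats(0.0, 1.0),
    )
    def test_preserves_total_mass(self, raw, v):
        pop = np.array(raw) / np.sum(raw)
        out = h.undirected_variation(pop, v)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)


class TestFitnessScores:
    def test_partner_absent_favours_wild_type(self):
        np.testing.assert_allclose(h.fitness_scores(5, 3.0, 0.0), [4, 3, 2, 1, 0])

    def test_baseline_absent_favours_mutualistic_type(self):
        np.testing.assert_allclose(h.fitness_scores(5, 0.0, 7.0), [1, 2, 3, 4, 5])

    def test_balance_point_is_neutral(self):
        np.testing.assert_allclose(h.fitness_scores(2, 1.0, 1.0), [1.0, 1.0])

    def test_zero_total_returns_ones(self):
        np.testing.assert_array_equal(h.fitness_scores(4, 0.0, 0.0), np.ones(4))

    def test_monotone_affine_in_index(self):
        scores = h.fitness_scores(7, 2.0, 5.0)
        diffs = np.diff(scores)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-12)

    def test_rejects_negative_utilities(self):
        with pytest.raises(ParameterError):
            h.fitness_scores(3, -1.0, 2.0)


class TestReplicatorUpdate:
    def test_neutral_selection_is_identity(self):
        pop = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(h.replicator_update(pop, np.ones(3)), pop, atol=1e-15)

    def test_hand_evaluated(self):
        out = h.replicator_update(np.array([0.5, 0.5]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [0.25, 0.75], atol=1e-15)

    def test_vertex_is_invariant(self):
        out = h.replicator_update(np.array([1.0, 0.0]), np.array([0.7, 9.0]))
        np.testing.assert_array_equal(out, [1.0, 0.0])

    def test_zero_mass_freezes_and_warns(self):
        pop = np.array([0.0, 1.0])
        fitness = np.array([5.0, 0.0])
        with pytest.warns(ReplicatorStagnationWarning):
            out = h.replicator_update(pop, fitness)
        np.testing.assert_array_equal(out, pop)


class TestStep:
    def test_decoupled_type1_start_moves_toward_baseline(self, decoupled_params):
        state = h.initial_state(decoupled_params)
        new_state, diag = h.step(state, decoupled_params)
        target = decoupled_params.utility_other_to_type_1_humans
        np.testing.assert_array_equal(
            new_state.type_proportions_humans, state.type_proportions_humans
        )
        assert diag.carrying_capacity_humans == pytest.approx(target)
        assert abs(new_state.humans - target) < abs(state.humans - target)

    def test_matches_independent_oracle_on_randomized_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(120):
            params = random_valid_params(rng)
            state = random_valid_state(params, rng)
            new_state, diag = h.step(state, params)
            expected = oracle_step(state, params)
            assert new_state.humans == pytest.approx(expected["humans"], abs=1e-10)
            assert new_state.plants == pytest.approx(expected["plants"], abs=1e-10)
            np.testing.assert_allclose(
                new_state.type_proportions_humans, expected["pop_humans"], atol=1e-10
            )
            np.testing.assert_allclose(
                new_state.type_proportions_plants, expected["pop_plants"], atol=1e-10
            )
            for key, attr in [
                ("U_HP", "utility_humans_to_plants"),
                ("U_PH", "utility_plants_to_humans"),
                ("U_bH", "utility_other_to_humans"),
                ("U_bP", "utility_other_to_plants"),
                ("K_H", "carrying_capacity_humans"),
                ("K_P", "carrying_capacity_plants"),
            ]:
                assert getattr(diag, attr) == pytest.approx(expected[key], abs=1e-10)
            np.testing.assert_allclose(diag.fitness_humans, expected["fitness_humans"], atol=1e-10)
            np.testing.assert_allclose(diag.fitness_plants, expected["fitness_plants"], atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_invariants_hold_along_trajectories(self, seed):
        """Proportions stay normalised and nonnegative; populations >= 0;
        the plant capacity never exceeds the area cap."""
        rng = np.random.default_rng(seed)
        params = replace(random_valid_params(rng), max_iterations=60)
        state = random_valid_state(params, rng)
        for _ in range(60):
            state, diag = h.step(state, params)
            assert state.humans >= 0 and state.plants >= 0
            for pop in (state.type_proportions_humans, state.type_proportions_plants):
                assert pop.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(pop >= 0)
            assert diag.carrying_capacity_plants <= params.max_area + 1e-12
            assert -1.0 <= diag.coevolution_coefficient_humans <= 1.0
            assert -1.0 <= diag.coevolution_coefficient_plants <= 1.0

    def test_structural_symmetry_under_block_swap(self):
        """With an infinite area cap, swapping the human/plant parameter
        blocks mirrors the trajectory (H <-> P, type mixes swapped)."""
        base = h.HPCParams(
            initial_population_humans=20.0,
            initial_population_plants=80.0,
            number_types_humans=4,
            number_types_plants=6,
            undirected_variation_humans=0.1,
            undirected_variation_plants=0.04,
            intrinsic_growth_rate_humans=0.2,
            intrinsic_growth_rate_plants=0.12,
            utility_per_capita_type_n_plants_to_humans=1.2,
            utility_per_capita_type_1_plants_to_humans=0.3,
            utility_per_capita_type_n_humans_to_plants=0.9,
            utility_per_capita_type_1_humans_to_plants=0.2,
            utility_other_to_type_n_plants=30.0,
            utility_other_to_type_1_plants=90.0,
            utility_other_to_type_n_humans=10.0,
            utility_other_to_type_1_humans=60.0,
            max_area=math.inf,
            max_iterations=200,
        )
        swapped = h.HPCParams(
            initial_population_humans=base.initial_population_plants,
            initial_population_plants=base.initial_population_humans,
            number_types_humans=base.number_types_plants,
            number_types_plants=base.number_types_humans,
            undirected_variation_humans=base.undirected_variation_plants,
            undirected_variation_plants=base.undirected_variation_humans,
            intrinsic_growth_rate_humans=base.intrinsic_growth_rate_plants,
            intrinsic_growth_rate_plants=base.intrinsic_growth_rate_humans,
            utility_per_capita_type_n_plants_to_humans=base.utility_per_capita_type_n_humans_to_plants,
            utility_per_capita_type_1_plants_to_humans=base.utility_per_capita_type_1_humans_to_plants,
            utility_per_capita_type_n_humans_to_plants=base.utility_per_capita_type_n_plants_to_humans,
            utility_per_capita_type_1_humans_to_plants=base.utility_per_capita_type_1_plants_to_humans,
            utility_other_to_type_n_plants=base.utility_other_to_type_n_humans,
            utility_other_to_type_1_plants=base.utility_other_to_type_1_humans,
            utility_other_to_type_n_humans=base.utility_other_to_type_n_plants,
            utility_other_to_type_1_humans=base.utility_other_to_type_1_plants,
            max_area=math.inf,
            max_iterations=200,
        )
        traj_a, _ = h.run(base)
        traj_b, _ = h.run(swapped)
        n = min(len(traj_a), len(traj_b))
        np.testing.assert_allclose(traj_a.humans[:n], traj_b.plants[:n], atol=1e-10)
        np.testing.assert_allclose(traj_a.plants[:n], traj_b.humans[:n], atol=1e-10)
        for t in range(0, n, 40):
            np.testing.assert_allclose(
                traj_a.states[t].type_proportions_humans,
                traj_b.states[t].type_proportions_plants,
                atol=1e-10,
            )


class TestParamValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"number_types_humans": 1},
            {"number_types_plants": 0},
            {"undirected_variation_humans": 1.5},
            {"undirected_variation_plants": -0.01},
            {"intrinsic_growth_rate_humans": -0.1},
            {"utility_per_capita_type_n_plants_to_humans": -1.0},
            {"max_area": 0.0},
            {"max_iterations": 0},
            {"reltol_exponential": 0.0},
            {"coevolution_threshold": 1.0},
            {"coevolution_threshold": -1.0},
        ],
    )
    def test_rejects_out_of_bound_parameters(self, overrides):
        with pytest.raises(ParameterError):
            h.HPCParams(**overrides)

    def test_rejects_denormalised_proportions(self, full_params):
        with pytest.raises(ParameterError):
            h.ModelState(
                humans=1.0,
                plants=1.0,
                type_proportions_humans=np.array([0.5, 0.6]),
                type_proportions_plants=np.array([0.5, 0.5]),
            )
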