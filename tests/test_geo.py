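"""Golden Eagle Optimization engine: geometry, contracts, convergence."""

import numpy as np
import pytest

from agebrf.geo import (
    Eagle,
    GEOConfig,
    PropensitySchedule,
    SearchSpace,
    attack_vector,
    cruise_vector,
    init_population,
    run_geo,
    select_prey,
    step_update,
)


def sphere(x):
    return float(np.sum(x * x))


def make_space(dim, lo=-1.0, hi=1.0):
    return SearchSpace(np.full(dim, lo), np.full(dim, hi))


class TestInitPopulation:
    def test_positions_within_bounds_and_memory_initialized(self):
        space = make_space(2, 0.0, 1.0)
        eagles = init_population(space, GEOConfig(5, 10, seed=7), sphere)
        assert len(eagles) == 5
        for e in eagles:
            assert space.contains(e.position)
            np.testing.assert_array_equal(e.position, e.memory_position)
            assert e.fitness == e.memory_fitness == sphere(e.position)

    def test_seeded_determinism(self):
        space = make_space(3)
        a = init_population(space, GEOConfig(5, 10, seed=7), sphere)
        b = init_population(space, GEOConfig(5, 10, seed=7), sphere)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.position, eb.position)

    def test_quadratic_fitness_range_over_box(self):
        # sum of squares over [-1, 1]^3 lies in [0, 3]
        eagles = init_population(make_space(3), GEOConfig(50, 10, seed=1), sphere)
        for e in eagles:
            assert 0.0 <= e.fitness <= 3.0

    def test_nonfinite_objective_at_init_is_an_error(self):
        with pytest.raises(ValueError, match="non-finite"):
            init_population(make_space(2), GEOConfig(3, 5, seed=0),
                            lambda x: float("nan"))


class TestSelectPrey:
    def test_single_eagle_selects_own_memory(self):
        e = Eagle(np.zeros(2), 0.0, np.ones(2), 1.0)
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(select_prey(0, [e], rng), e.memory_position)

    def test_uniform_selection_frequency(self):
        rng = np.random.default_rng(42)
        eagles = [Eagle(np.full(1, float(i)), 0.0, np.full(1, float(i)), 0.0)
                  for i in range(10)]
        hits = np.zeros(10)
        for _ in range(10_000):
            prey = select_prey(0, eagles, rng)
            hits[int(prey[0])] += 1
        freqs = hits / 10_000
        assert np.all(np.abs(freqs - 0.1) < 0.02)

    def test_prey_is_a_memory_position_not_a_raw_position(self):
        rng = np.random.default_rng(3)
        eagles = [Eagle(rng.uniform(size=2), 0.0, rng.uniform(size=2), 0.0)
                  for _ in range(6)]
        memories = {tuple(e.memory_position) for e in eagles}
        positions = {tuple(e.position) for e in eagles}
        for _ in range(100):
            prey = tuple(select_prey(0, eagles, rng))
            assert prey in memories
            assert prey not in positions

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            select_prey(0, [], np.random.default_rng(0))


class TestAttackVector:
    def test_eagle_at_prey_gives_zero(self):
        e = Eagle(np.array([1.0, 1.0]), 0.0, np.array([1.0, 1.0]), 0.0)
        np.testing.assert_array_equal(attack_vector(e, np.array([1.0, 1.0])),
                                      np.zeros(2))

    def test_three_four_five_norm(self):
        e = Eagle(np.zeros(2), 0.0, np.zeros(2), 0.0)
        a = attack_vector(e, np.array([3.0, 4.0]))
        np.testing.assert_array_equal(a, [3.0, 4.0])
        assert np.linalg.norm(a) == 5.0

    def test_algebraic_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pos = rng.normal(size=4)
            prey = rng.normal(size=4)
            e = Eagle(pos, 0.0, pos, 0.0)
            np.testing.assert_allclose(attack_vector(e, prey) + pos, prey)

    def test_dimension_mismatch(self):
        e = Eagle(np.zeros(2), 0.0, np.zeros(2), 0.0)
        with pytest.raises(ValueError):
            attack_vector(e, np.zeros(3))


class TestCruiseVector:
    def test_degenerate_attack_gives_unit_direction(self):
        rng = np.random.default_rng(0)
        e = Eagle(np.array([0.3, 0.4]), 0.0, np.array([0.3, 0.4]), 0.0)
        c = cruise_vector(e, np.zeros(2), make_space(2), rng)
        assert np.isclose(np.linalg.norm(c), 1.0)

    def test_orthogonality_hand_case(self):
        rng = np.random.default_rng(0)
        e = Eagle(np.zeros(2), 0.0, np.zeros(2), 0.0)
        attack = np.array([3.0, 4.0])
        c = cruise_vector(e, attack, make_space(2, -5, 5), rng)
        cosine = abs(c @ attack) / (np.linalg.norm(c) * 5.0)
        assert cosine < 1e-8

    def test_orthogonality_property_sweep(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            dim = int(rng.integers(2, 11))
            space = make_space(dim, -5.0, 5.0)
            pos = rng.uniform(-5, 5, dim)
            attack = rng.normal(size=dim)
            e = Eagle(pos, 0.0, pos, 0.0)
            c = cruise_vector(e, attack, space, rng)
            na, nc = np.linalg.norm(attack), np.linalg.norm(c)
            assert nc > 0
            assert abs(c @ attack) / (na * nc) < 1e-8


class TestStepUpdate:
    def test_zero_propensities_and_degenerate_vectors_keep_position(self):
        sched = PropensitySchedule(0.0, 0.0, 0.0, 0.0, T=10)
        pos = np.array([0.2, -0.3])
        e = Eagle(pos.copy(), 0.0, pos.copy(), 0.0)
        new = step_update(e, np.zeros(2), np.zeros(2), 0, sched,
                          np.random.default_rng(0), make_space(2))
        np.testing.assert_array_equal(new, pos)

    def test_step_norm_bounded_by_propensities_times_attack_norm(self):
        rng = np.random.default_rng(7)
        sched = PropensitySchedule(T=10)
        space = make_space(4, -100.0, 100.0)  # wide: no clipping interference
        for _ in range(500):
            pos = rng.uniform(-1, 1, 4)
            e = Eagle(pos, 0.0, pos, 0.0)
            attack = rng.normal(size=4)
            cruise = cruise_vector(e, attack, space, rng)
            t = float(rng.uniform(0, 10))
            new = step_update(e, attack, cruise, t, sched, rng, space)
            bound = (sched.pa(t) + sched.pc(t)) * np.linalg.norm(attack)
            assert np.linalg.norm(new - pos) <= bound + 1e-9

    def test_positions_respect_bounds(self):
        rng = np.random.default_rng(11)
        sched = PropensitySchedule(T=5)
        space = make_space(3, -0.5, 0.5)
        for _ in range(1000):
            pos = rng.uniform(-0.5, 0.5, 3)
            e = Eagle(pos, 0.0, pos, 0.0)
            attack = rng.normal(size=3) * 10
            cruise = cruise_vector(e, attack, space, rng)
            new = step_update(e, attack, cruise, 2.0, sched, rng, space)
            assert space.contains(new)


class TestRunGeo:
    @pytest.mark.parametrize("objective", [
        sphere,
        lambda x: float(np.sum(np.abs(x))),
        lambda x: float(np.sum((x - 0.5) ** 2) + 1.0),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_history_non_increasing(self, objective, seed):
        res = run_geo(make_space(3, -2, 2), GEOConfig(10, 30, seed=seed), objective)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert res.best_fitness == res.history[-1]

    def test_constant_objective(self):
        res = run_geo(make_space(2), GEOConfig(2, 1, seed=0), lambda x: 3.25)
        assert res.best_fitness == 3.25
        assert res.history == [3.25]

    def test_seeded_determinism_bit_identical(self):
        cfg = GEOConfig(8, 20, seed=99)
        a = run_geo(make_space(4, -3, 3), cfg, sphere)
        b = run_geo(make_space(4, -3, 3), cfg, sphere)
        assert a.to_json() == b.to_json()

    def test_nonfinite_objective_after_init_treated_as_inf(self):
        calls = {"n": 0}

        def spiky(x):
            calls["n"] += 1
            if calls["n"] > 5 and x[0] > 0:  # finite during initialization
                return float("inf")
            return sphere(x)

        res = run_geo(make_space(2), GEOConfig(5, 10, seed=4), spiky)
        assert np.isfinite(res.best_fitness)

    def test_initial_position_elitism(self):
        start = np.array([0.01, -0.01])
        res = run_geo(make_space(2), GEOConfig(4, 5, seed=0), sphere,
                      initial_positions=[start])
        assert res.best_fitness <= sphere(start) + 1e-12

    def test_result_json_round_trip(self):
        from agebrf.geo import GEOResult

        res = run_geo(make_space(2), GEOConfig(4, 5, seed=1), sphere)
        again = GEOResult.from_json(res.to_json())
        assert again.to_json() == res.to_json()
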