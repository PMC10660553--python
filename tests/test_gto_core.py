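"""Unit and property tests for the troop-based optimizer core.

The replay oracles below re-derive every candidate position by hand from
the documented RNG draw order, independently of the implementation.
"""

import numpy as np
import pytest

from gtoscreen.gto_core import (
    GTOCoefficients,
    GTOParams,
    Population,
    competition_update,
    compute_coefficients,
    exploration_update,
    follow_silverback_update,
    gto_step,
    init_population,
    optimize,
)


def _pop(solutions, scores, lb=0.0, ub=1.0):
    solutions = np.asarray(solutions, dtype=float)
    D = solutions.shape[1]
    return Population(
        solutions=solutions,
        scores=np.asarray(scores, dtype=float),
        lb=np.full(D, lb),
        ub=np.full(D, ub),
    )


class TestInitPopulation:
    def test_components_within_box(self, rng):
        pop = init_population(8, 5, 0.0, 1.0, rng)
        assert pop.solutions.shape == (8, 5)
        assert np.all(pop.solutions >= 0.0) and np.all(pop.solutions <= 1.0)

    def test_degenerate_box_is_constant(self, rng):
        pop = init_population(4, 3, 0.3, 0.3, rng)
        assert np.all(pop.solutions == 0.3)

    def test_same_seed_bitwise_identical(self):
        a = init_population(5, 4, -1.0, 2.0, np.random.default_rng(9))
        b = init_population(5, 4, -1.0, 2.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a.solutions, b.solutions)

    def test_invalid_bounds_raise(self, rng):
        with pytest.raises(ValueError, match="LB > UB"):
            init_population(3, 2, 1.0, 0.0, rng)

    def test_uniform_scaling_matches_formula(self):
        # rand*(UB-LB)+LB with the same stream
        r1 = np.random.default_rng(4).random((6, 2))
        pop = init_population(6, 2, -2.0, 3.0, np.random.default_rng(4))
        np.testing.assert_allclose(pop.solutions, r1 * 5.0 - 2.0)


class TestCoefficients:
    def test_decay_reaches_zero_at_final_iteration(self, rng):
        c = compute_coefficients(25, 25, 3.0, rng)
        assert c.C == 0.0
        assert c.L == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_impact_force_in_unit_interval(self, seed):
        c = compute_coefficients(1, 10, 3.0, np.random.default_rng(seed))
        assert -1.0 <= c.Q <= 1.0

    def test_fixed_seed_identical_stream(self):
        a = [compute_coefficients(1, 5, 3.0, np.random.default_rng(7), dim=3)
             for _ in range(1)]
        b = [compute_coefficients(1, 5, 3.0, np.random.default_rng(7), dim=3)
             for _ in range(1)]
        assert a[0].C == b[0].C and a[0].L == b[0].L and a[0].Q == b[0].Q
        np.testing.assert_array_equal(a[0].A, b[0].A)

    def test_iteration_out_of_range_raises(self, rng):
        with pytest.raises(ValueError, match="outside"):
            compute_coefficients(0, 10, 3.0, rng)
        with pytest.raises(ValueError, match="outside"):
            compute_coefficients(11, 10, 3.0, rng)

    def test_draw_order_replay(self):
        """C, L, Q, A replayed by hand from the documented draw order."""
        rng = np.random.default_rng(42)
        r4 = rng.random()
        l = rng.uniform(-1.0, 1.0)
        r5 = rng.random()
        branch = rng.random()
        E = rng.standard_normal(4) if branch >= 0.5 else float(rng.standard_normal())
        t, Tmax, beta = 3, 10, 3.0
        C = (np.cos(2 * r4) + 1) * (1 - t / Tmax)
        got = compute_coefficients(t, Tmax, beta, np.random.default_rng(42), dim=4)
        assert got.C == pytest.approx(C)
        assert got.L == pytest.approx(C * l)
        assert got.Q == pytest.approx(2 * r5 - 1)
        np.testing.assert_allclose(np.atleast_1d(got.A), np.atleast_1d(beta * E))


def _replay_exploration(x, pop, C, L, p, rng):
    """Independent hand evaluation of the three exploration mechanisms."""
    lb, ub = pop.lb, pop.ub
    D = len(x)
    if rng.random() < p:
        branch = "migrate"
        cand = lb + rng.random(D) * (ub - lb)
    elif rng.random() >= 0.5:
        branch = "peer"
        xr = pop.solutions[int(rng.integers(pop.size))]
        r2 = rng.random()
        Z = rng.uniform(-C, C, D)
        cand = L * (Z * x) + (r2 - C) * xr
    else:
        branch = "known"
        xr = pop.solutions[int(rng.integers(pop.size))]
        r3 = rng.random()
        cand = x - L * (L * (x - xr) + r3 * (x - xr))
    return np.clip(cand, lb, ub), branch


class TestExplorationUpdate:
    def test_forced_migration_is_uniform_resample(self):
        pop = _pop([[0.2, 0.2], [0.8, 0.8]], [1.0, 2.0])
        rng = np.random.default_rng(0)
        coeffs = GTOCoefficients(C=0.5, L=0.2, Q=0.1, A=1.0)
        cand = exploration_update(pop.solutions[0], pop, coeffs, p=1.0, rng=rng)
        replay = np.random.default_rng(0)
        replay.random()  # the migration decision
        expected = pop.lb + replay.random(2) * (pop.ub - pop.lb)
        np.testing.assert_allclose(cand, expected)

    def test_degenerate_box_clips_to_constant(self):
        pop = _pop([[0.3, 0.3], [0.3, 0.3]], [1.0, 2.0], lb=0.3, ub=0.3)
        coeffs = GTOCoefficients(C=1.2, L=0.7, Q=0.1, A=2.0)
        for seed in range(10):
            cand = exploration_update(
                pop.solutions[0], pop, coeffs, p=0.3,
                rng=np.random.default_rng(seed),
            )
            np.testing.assert_array_equal(cand, 0.3)

    @pytest.mark.parametrize("seed", range(30))
    def test_candidates_match_hand_replay(self, seed):
        """Every candidate equals the hand evaluation of the selected branch."""
        pop = _pop([[0.1, 0.9], [0.6, 0.4]], [2.0, 1.0])
        coeffs = GTOCoefficients(C=0.8, L=0.3, Q=0.0, A=1.0)
        got = exploration_update(
            pop.solutions[0], pop, coeffs, p=0.1, rng=np.random.default_rng(seed)
        )
        want, _ = _replay_exploration(
            pop.solutions[0], pop, coeffs.C, coeffs.L, 0.1,
            np.random.default_rng(seed),
        )
        np.testing.assert_allclose(got, want)

    def test_branch_frequencies_match_mechanism_probabilities(self):
        """Over 10,000 draws with p=0.03 the empirical branch split matches
        (p, (1-p)/2, (1-p)/2) within 3 standard errors."""
        p = 0.03
        pop = _pop([[0.1, 0.9], [0.6, 0.4]], [2.0, 1.0])
        coeffs = GTOCoefficients(C=0.8, L=0.3, Q=0.0, A=1.0)
        n = 10_000
        counts = {"migrate": 0, "peer": 0, "known": 0}
        for seed in range(n):
            impl = exploration_update(
                pop.solutions[0], pop, coeffs, p, np.random.default_rng(seed)
            )
            want, branch = _replay_exploration(
                pop.solutions[0], pop, coeffs.C, coeffs.L, p,
                np.random.default_rng(seed),
            )
            np.testing.assert_allclose(impl, want)
            counts[branch] += 1
        expected = {"migrate": p, "peer": (1 - p) / 2, "known": (1 - p) / 2}
        for branch, q in expected.items():
            se = np.sqrt(q * (1 - q) / n)
            assert abs(counts[branch] / n - q) < 3 * se, (branch, counts)


class TestExploitationUpdates:
    def test_silverback_is_fixed_point_of_following(self):
        pop = _pop([[0.2], [0.8]], [0.5, 1.5])
        coeffs = GTOCoefficients(C=0.5, L=0.4, Q=0.0, A=1.0)
        cand = follow_silverback_update(pop.silverback, pop, coeffs)
        np.testing.assert_allclose(cand, pop.silverback)

    def test_zero_amplitude_keeps_every_member(self):
        pop = _pop([[0.2, 0.7], [0.8, 0.1]], [0.5, 1.5])
        coeffs = GTOCoefficients(C=0.5, L=0.0, Q=0.0, A=1.0)
        for i in range(pop.size):
            cand = follow_silverback_update(pop.solutions[i], pop, coeffs)
            np.testing.assert_allclose(cand, pop.solutions[i])

    def test_following_matches_direct_arithmetic(self):
        # mean of {0.2, 1.8} is 1, so the troop magnitude M is exactly 1
        pop = _pop([[0.2], [1.8]], [0.1, 0.9], lb=0.0, ub=2.0)
        coeffs = GTOCoefficients(C=0.5, L=0.5, Q=0.0, A=1.0)
        cand = follow_silverback_update(np.array([0.4]), pop, coeffs)
        # 0.5 * 1 * (0.4 - 0.2) + 0.4
        np.testing.assert_allclose(cand, [0.5])

    def test_zero_impact_force_returns_silverback(self):
        coeffs = GTOCoefficients(C=0.5, L=0.2, Q=0.0, A=1.7)
        cand = competition_update(np.array([0.3]), np.array([0.9]), coeffs)
        np.testing.assert_allclose(cand, [0.9])

    def test_competition_at_silverback_is_fixed_point(self):
        sb = np.array([0.4, 0.6])
        coeffs = GTOCoefficients(C=0.5, L=0.2, Q=0.8, A=2.0)
        np.testing.assert_allclose(competition_update(sb, sb, coeffs), sb)

    def test_competition_matches_direct_arithmetic(self):
        coeffs = GTOCoefficients(C=0.5, L=0.2, Q=0.5, A=1.0)
        cand = competition_update(np.array([0.2]), np.array([0.8]), coeffs)
        # 0.8 - (0.8*0.5 - 0.2*0.5) * 1
        np.testing.assert_allclose(cand, [0.5])

    def test_empty_population_raises(self):
        pop = Population(
            solutions=np.empty((0, 1)), scores=np.empty(0),
            lb=np.zeros(1), ub=np.ones(1),
        )
        with pytest.raises(ValueError, match="silverback"):
            follow_silverback_update(np.array([0.5]), pop,
                                     GTOCoefficients(0.5, 0.2, 0.0, 1.0))


class TestStepAndOptimize:
    def test_constant_fitness_leaves_population_unchanged(self, rng):
        pop = init_population(5, 3, 0.0, 1.0, rng)
        pop.scores[:] = 1.0
        before = pop.solutions.copy()
        gto_step(pop, 1, GTOParams(Nmax=5, Tmax=4, seed=0), lambda x: 1.0, rng)
        np.testing.assert_array_equal(pop.solutions, before)

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_step_never_worsens_best(self, seed):
        rng = np.random.default_rng(seed)
        pop = init_population(6, 2, 0.0, 1.0, rng)
        f = lambda x: float(np.sum(x**2))
        pop.scores = np.array([f(s) for s in pop.solutions])
        best_before = pop.best_score
        gto_step(pop, 1, GTOParams(Nmax=6, Tmax=3, seed=seed), f, rng)
        assert pop.best_score <= best_before

    def test_bounds_preserved_through_whole_run(self):
        lb, ub = np.array([-1.0, 2.0]), np.array([0.5, 7.0])
        seen = []
        def f(x):
            seen.append(x.copy())
            return float(np.sum(x**2))
        optimize(f, GTOParams(Nmax=6, Tmax=8, seed=5), D=2, LB=lb, UB=ub)
        allx = np.array(seen)
        assert np.all(allx >= lb - 1e-12) and np.all(allx <= ub + 1e-12)

    def test_history_contract(self):
        res = optimize(lambda x: float(np.sum(x**2)),
                       GTOParams(Nmax=4, Tmax=12, seed=1), D=3, LB=0.0, UB=1.0)
        assert len(res.history) == 12
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert res.best_score == min(res.history)

    def test_zero_iterations_returns_best_initial_sample(self):
        f = lambda x: float(np.sum(x**2))
        res = optimize(f, GTOParams(Nmax=5, Tmax=0, seed=3), D=2, LB=0.0, UB=1.0)
        rng = np.random.default_rng(3)
        init = rng.random((5, 2))
        assert res.best_score == pytest.approx(min(f(s) for s in init))
        assert res.evaluations == 5

    def test_identical_seed_identical_result(self):
        f = lambda x: float(np.sum((x - 0.3) ** 2))
        a = optimize(f, GTOParams(Nmax=5, Tmax=10, seed=77), D=4, LB=0.0, UB=1.0)
        b = optimize(f, GTOParams(Nmax=5, Tmax=10, seed=77), D=4, LB=0.0, UB=1.0)
        assert a.best_score == b.best_score
        np.testing.assert_array_equal(a.best_solution, b.best_solution)
        assert a.history == b.history and a.evaluations == b.evaluations

    @pytest.mark.parametrize("seed", range(25))
    def test_optimizer_improves_on_initial_sample(self, seed):
        """Final best beats the best initial sample on the shifted sphere."""
        f = lambda x: float(np.sum((x - 0.5) ** 2))
        res = optimize(f, GTOParams(seed=seed), D=3, LB=0.0, UB=1.0)
        init = np.random.default_rng(seed).random((10, 3))
        assert res.best_score <= min(f(s) for s in init)

    def test_fitness_error_carries_solution_index(self):
        from gtoscreen.gto_core import FitnessEvaluationError

        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(FitnessEvaluationError, match="solution 0"):
            optimize(bad, GTOParams(Nmax=3, Tmax=1, seed=0), D=2, LB=0.0, UB=1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GTOParams(Nmax=1)
        with pytest.raises(ValueError):
            GTOParams(p=1.5)
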