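import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from firehawk.optimizer import (
    AdaptiveSchedule,
    ConfigurationError,
    DimensionError,
    OptimizerConfig,
    Population,
    SearchSpace,
    adaptive_factor,
    assign_territories,
    clamp_to_bounds,
    draw_hawk_count,
    global_safe_place,
    hawk_step,
    hawk_step_adaptive,
    initialize_population,
    local_safe_place,
    pairwise_distance,
    prey_step_outside,
    prey_step_within,
    run_optimizer,
)


def unit_square():
    return SearchSpace(lower=np.zeros(2), upper=np.ones(2))


class TestSearchSpace:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(lower=np.array([1.0, 0.0]), upper=np.array([0.0, 1.0]))

    def test_dimension(self):
        assert unit_square().d == 2


class TestInitializePopulation:
    def test_bounds_containment(self, rng):
        pop = initialize_population(unit_square(), 5, rng)
        assert pop.positions.shape == (5, 2)
        assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_zero_width_interval(self, rng):
        space = SearchSpace(lower=np.array([3.0, 3.0]), upper=np.array([3.0, 3.0]))
        pop = initialize_population(space, 4, rng)
        assert (pop.positions == 3.0).all()

    def test_seeded_reproducibility(self):
        a = initialize_population(unit_square(), 6, np.random.default_rng(7)).positions
        b = initialize_population(unit_square(), 6, np.random.default_rng(7)).positions
        np.testing.assert_array_equal(a, b)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            initialize_population(unit_square(), 1, rng)


class TestDrawHawkCount:
    def test_pop_two_forces_one(self, rng):
        assert all(draw_hawk_count(2, 0.2, rng) == 1 for _ in range(50))

    def test_clamp_bound(self, rng):
        counts = {draw_hawk_count(25, 0.2, rng) for _ in range(500)}
        assert counts <= {1, 2, 3, 4, 5}

    def test_distribution_matches_clamped_half_normal(self):
        # closed-form probabilities of clamp(round(|Z|*N/5), 1, 20) at N=100
        rng = np.random.default_rng(99)
        n_draws, pop = 10_000, 100
        draws = np.array([draw_hawk_count(pop, 0.2, rng) for _ in range(n_draws)])
        scale = pop / 5.0
        probs = np.zeros(20)
        for j in range(1, 21):
            if j == 1:
                probs[0] = stats.halfnorm.cdf(1.5 / scale)
            elif j == 20:
                probs[19] = stats.halfnorm.sf(19.5 / scale)
            else:
                probs[j - 1] = stats.halfnorm.cdf((j + 0.5) / scale) - stats.halfnorm.cdf(
                    (j - 0.5) / scale
                )
        observed = np.bincount(draws, minlength=21)[1:21]
        # pool tiny-expectation bins to keep the chi-square valid
        keep = probs * n_draws >= 5
        obs, exp = observed[keep], probs[keep] * n_draws
        if (~keep).any():
            obs = np.append(obs, observed[~keep].sum())
            exp = np.append(exp, probs[~keep].sum() * n_draws)
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert chi2 < stats.chi2.ppf(0.99, df=len(obs) - 1)


class TestPairwiseDistance:
    def test_three_four_five(self):
        assert pairwise_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_identity(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pairwise_distance(a, a) == 0.0

    def test_three_dimensional(self):
        # sqrt(9 + 16 + 0) = 5
        assert pairwise_distance(np.array([1.0, 2.0, 3.0]), np.array([4.0, 6.0, 3.0])) == pytest.approx(5.0)

    def test_mismatch(self):
        with pytest.raises(DimensionError):
            pairwise_distance(np.zeros(2), np.zeros(3))

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=6),
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=6),
    )
    def test_symmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = np.array(xs[:n]), np.array(ys[:n])
        assert pairwise_distance(a, b) == pairwise_distance(b, a)


class TestAssignTerritories:
    def test_single_hawk_takes_all(self, rng):
        pop = Population(rng.random((6, 2)))
        state = assign_territories(pop, [0], [1, 2, 3, 4, 5])
        assert state.assignment[0] == [1, 2, 3, 4, 5]

    def test_tie_goes_to_better_ranked_hawk(self):
        positions = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        state = assign_territories(Population(positions), [0, 1], [2])
        assert state.assignment[0] == [2]
        assert state.assignment[1] == []

    def test_matches_bruteforce_enumeration(self, rng):
        positions = rng.random((10, 3))
        hawks, prey = [0, 1, 2], list(range(3, 10))
        state = assign_territories(Population(positions), hawks, prey)
        for q in prey:
            dists = [pairwise_distance(positions[q], positions[h]) for h in hawks]
            expected_owner = hawks[int(np.argmin(dists))]
            assert q in state.assignment[expected_owner]
        assigned = sorted(i for members in state.assignment.values() for i in members)
        assert assigned == prey

    def test_empty_hawk_set_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            assign_territories(Population(rng.random((3, 2))), [], [0, 1, 2])


class _FixedUniform:
    """Stub RNG yielding a fixed sequence of uniforms."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)


class TestHawkStep:
    def test_zero_step(self):
        out = hawk_step(np.array([1.0, 1.0]), np.ones(2), np.ones(2), _FixedUniform([0.0, 0.0]))
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_cancellation(self):
        x = np.array([0.3, 0.7])
        out = hawk_step(x, x, x, _FixedUniform([0.4, 0.4]))
        np.testing.assert_allclose(out, x)

    def test_arithmetic(self):
        out = hawk_step(
            np.array([1.0, 1.0]), np.zeros(2), np.array([2.0, 2.0]), _FixedUniform([0.5, 0.25])
        )
        np.testing.assert_allclose(out, [0.5, 0.5])


class TestAdaptiveFactor:
    def test_unity_at_zero(self):
        for alpha in (0.05, 0.3, 0.9):
            assert adaptive_factor(AdaptiveSchedule(alpha0=alpha, alpha_end=0.95, gamma=0.7), 0) == 1.0

    def test_gamma_zero_constant(self):
        sched = AdaptiveSchedule(alpha0=0.2, gamma=0.0)
        assert all(adaptive_factor(sched, t) == 1.0 for t in (0, 1, 10, 1000))

    def test_analytic_value(self):
        # 0.2 + 0.8 * exp(-1)
        f = adaptive_factor(AdaptiveSchedule(alpha0=0.2, gamma=0.5), 2)
        assert f == pytest.approx(0.2 + 0.8 * math.exp(-1.0), abs=1e-12)
        assert f == pytest.approx(0.494303, abs=1e-6)

    def test_limit_is_alpha(self):
        sched = AdaptiveSchedule(alpha0=0.15, gamma=2.0)
        assert adaptive_factor(sched, 10_000) == pytest.approx(0.15, abs=1e-12)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.0, 5.0),
        st.integers(0, 500),
    )
    @settings(max_examples=200)
    def test_bounded_and_monotone(self, alpha, gamma, t):
        sched = AdaptiveSchedule(alpha0=alpha, alpha_end=1.0, gamma=gamma)
        f_t = adaptive_factor(sched, t)
        assert min(alpha, 1.0) - 1e-12 <= f_t <= 1.0 + 1e-12
        assert adaptive_factor(sched, t + 1) <= f_t + 1e-12

    def test_linear_mode_ramps_alpha(self):
        sched = AdaptiveSchedule(alpha0=0.1, alpha_end=0.9, gamma=1000.0, mode="linear_alpha")
        # huge gamma kills the exp term for t >= 1, exposing alpha(t)
        assert adaptive_factor(sched, 50, max_iters=100) == pytest.approx(0.5, abs=1e-9)


class TestHawkStepAdaptive:
    def test_t_zero_matches_plain_step(self):
        args = (np.array([1.0, 2.0]), np.array([0.5, 0.5]), np.array([2.0, 0.0]))
        plain = hawk_step(*args, _FixedUniform([0.3, 0.6]))
        adaptive = hawk_step_adaptive(*args, AdaptiveSchedule(), 0, _FixedUniform([0.3, 0.6]))
        np.testing.assert_array_equal(plain, adaptive)

    def test_large_gamma_scales_by_alpha(self):
        hawk, gb, near = np.array([1.0, 1.0]), np.zeros(2), np.array([2.0, 2.0])
        sched = AdaptiveSchedule(alpha0=0.25, gamma=1e9)
        out = hawk_step_adaptive(hawk, gb, near, sched, 1, _FixedUniform([0.5, 0.25]))
        np.testing.assert_allclose(out, hawk + np.array([-0.5, -0.5]) * 0.25)

    def test_half_factor_arithmetic(self):
        # step (-0.5,-0.5) scaled by f=0.5 -> (0.75, 0.75)
        hawk, gb, near = np.array([1.0, 1.0]), np.zeros(2), np.array([2.0, 2.0])
        sched = AdaptiveSchedule(alpha0=0.5, gamma=1e9)
        out = hawk_step_adaptive(hawk, gb, near, sched, 5, _FixedUniform([0.5, 0.25]))
        np.testing.assert_allclose(out, [0.75, 0.75])


class TestSafePlaces:
    def test_single_prey(self):
        np.testing.assert_array_equal(local_safe_place(np.array([[0.2, 0.8]])), [0.2, 0.8])

    def test_midpoint(self):
        prey = np.array([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_array_equal(local_safe_place(prey), [1.0, 1.0])

    def test_matches_summation_oracle(self, rng):
        prey = rng.random((5, 3))
        expected = np.array([prey[:, j].sum() / 5 for j in range(3)])
        np.testing.assert_allclose(local_safe_place(prey), expected)
        np.testing.assert_allclose(global_safe_place(prey), expected)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            local_safe_place(np.empty((0, 2)))


class TestPreySteps:
    def test_zero_step(self):
        p = np.array([0.1, 0.9])
        np.testing.assert_array_equal(
            prey_step_within(p, np.ones(2), np.ones(2), _FixedUniform([0.0, 0.0])), p
        )
        np.testing.assert_array_equal(
            prey_step_outside(p, np.ones(2), np.ones(2), _FixedUniform([0.0, 0.0])), p
        )

    def test_cancellation(self):
        p, h = np.array([0.4, 0.4]), np.array([0.6, 0.2])
        np.testing.assert_allclose(prey_step_within(p, h, h, _FixedUniform([0.7, 0.7])), p)

    def test_arithmetic(self):
        out = prey_step_within(
            np.zeros(2), np.array([1.0, 0.0]), np.array([0.0, 1.0]), _FixedUniform([0.5, 0.5])
        )
        np.testing.assert_allclose(out, [0.5, -0.5])
        out = prey_step_outside(
            np.zeros(2), np.array([1.0, 0.0]), np.array([0.0, 1.0]), _FixedUniform([0.5, 0.5])
        )
        np.testing.assert_allclose(out, [0.5, -0.5])


class TestClampToBounds:
    def test_in_bounds_unchanged(self):
        x = np.array([0.25, 0.75])
        np.testing.assert_array_equal(clamp_to_bounds(x, unit_square()), x)

    def test_clip(self):
        np.testing.assert_array_equal(
            clamp_to_bounds(np.array([-5.0, 2.0]), unit_square()), [0.0, 1.0]
        )

    def test_random_positions_always_feasible(self, rng):
        space = SearchSpace(lower=np.array([-1.0, 2.0]), upper=np.array([1.0, 5.0]))
        for _ in range(1000):
            out = clamp_to_bounds(rng.normal(0, 10, size=2), space)
            assert (out >= space.lower).all() and (out <= space.upper).all()


class TestRunOptimizer:
    def test_constant_objective(self):
        space = unit_square()
        config = OptimizerConfig(pop_size=8, max_iters=15, seed=3)
        result = run_optimizer(lambda x: 4.25, space, config)
        assert result.best_value == 4.25
        assert all(v == 4.25 for v in result.history)

    def test_history_monotone(self):
        space = SearchSpace(lower=np.full(3, -5.0), upper=np.full(3, 5.0))
        for seed in range(5):
            config = OptimizerConfig(pop_size=10, max_iters=40, seed=seed)
            result = run_optimizer(lambda x: float(np.sum(x**2)), space, config)
            assert all(b <= a + 1e-15 for a, b in zip(result.history, result.history[1:]))

    def test_seeded_reproducibility(self):
        space = SearchSpace(lower=np.full(2, -3.0), upper=np.full(2, 3.0))
        config = OptimizerConfig(pop_size=10, max_iters=25, seed=11)
        obj = lambda x: float(np.sum(x**2))  # noqa: E731
        a = run_optimizer(obj, space, config)
        b = run_optimizer(obj, space, config)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.history == b.history

    def test_beats_random_search_on_sphere(self):
        # convergence oracle: elitist scheme must clearly outrun blind sampling
        space = SearchSpace(lower=np.full(2, -5.12), upper=np.full(2, 5.12))
        obj = lambda x: float(np.sum((x - 1.3) ** 2))  # noqa: E731
        config = OptimizerConfig(pop_size=20, max_iters=100, seed=0)
        result = run_optimizer(obj, space, config)
        rng = np.random.default_rng(0)
        n_rand = result.evaluations
        rand_best = min(
            obj(space.lower + rng.random(2) * (space.upper - space.lower)) for _ in range(n_rand)
        )
        assert result.best_value < rand_best / 10

    def test_maximize_direction(self):
        space = unit_square()
        config = OptimizerConfig(pop_size=10, max_iters=30, direction="maximize", seed=5)
        result = run_optimizer(lambda x: -float(np.sum((x - 0.5) ** 2)), space, config)
        assert result.best_value == pytest.approx(0.0, abs=1e-3)
        assert all(b >= a for a, b in zip(result.history, result.history[1:]))

    def test_non_finite_objective_ranked_worst(self):
        space = unit_square()

        def obj(x):
            return math.nan if x[0] > 0.5 else float(x[0])

        config = OptimizerConfig(pop_size=10, max_iters=10, seed=2)
        result = run_optimizer(obj, space, config)
        assert math.isfinite(result.best_value)

    def test_max_evals_stops_early(self):
        space = unit_square()
        config = OptimizerConfig(pop_size=10, max_iters=1000, max_evals=200, seed=1)
        result = run_optimizer(lambda x: float(x[0]), space, config)
        assert result.evaluations <= 200 + 3 * 10  # at most one extra iteration of proposals

    def test_ifho_fho_identical_first_iteration(self):
        space = SearchSpace(lower=np.full(2, -2.0), upper=np.full(2, 2.0))
        obj = lambda x: float(np.sum(x**2))  # noqa: E731
        states = {}
        for variant in ("fho", "ifho"):
            captured = []
            config = OptimizerConfig(pop_size=12, max_iters=1, variant=variant, seed=21)
            run_optimizer(obj, space, config, iteration_callback=captured.append)
            states[variant] = captured[0]
        np.testing.assert_array_equal(states["fho"]["positions"], states["ifho"]["positions"])
        np.testing.assert_array_equal(states["fho"]["values"], states["ifho"]["values"])

    def test_population_size_conserved_and_feasible(self):
        space = SearchSpace(lower=np.full(3, -4.0), upper=np.full(3, 4.0))
        config = OptimizerConfig(pop_size=9, max_iters=25, seed=8)

        def check(state):
            assert state["positions"].shape == (9, 3)
            assert (state["positions"] >= space.lower).all()
            assert (state["positions"] <= space.upper).all()

        run_optimizer(lambda x: float(np.sum(np.abs(x))), space, config, iteration_callback=check)
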