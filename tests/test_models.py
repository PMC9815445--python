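import numpy as np
import pytest

from lvmar.models import (DivergenceError, LVParameters, MARParameters,
                          NoiseSpec, SimulationGrid, SingularMatrixError,
                          Trajectory, draw_process_noise, lv_steady_state,
                          lv_to_mar_steady_map, mar_steady_state,
                          shape_for_noise_sd, simulate_lv_discrete,
                          simulate_lv_ode, simulate_mar)


class TestLVOde:
    def test_steady_start_stays_constant(self, logistic_params):
        grid = SimulationGrid.over_span(0, 5, 50)
        traj = simulate_lv_ode(logistic_params, [2.0], grid)
        assert np.allclose(traj.values, 2.0, atol=1e-8)

    def test_logistic_closed_form(self, logistic_params):
        # x(t) = K / (1 + (K/x0 - 1) e^{-at}), K = 2: at t = ln 3, x = 1.5
        grid = SimulationGrid(start_time=0.0, step=np.log(3.0), n_steps=1)
        traj = simulate_lv_ode(logistic_params, [1.0], grid)
        assert traj.values[-1, 0] == pytest.approx(1.5, abs=1e-8)

    def test_zero_dynamics_constant(self):
        p = LVParameters(np.zeros(2), np.zeros((2, 2)))
        traj = simulate_lv_ode(p, [3.0, 7.0], SimulationGrid.over_span(0, 4, 10))
        assert np.allclose(traj.values, [3.0, 7.0])

    def test_dimension_mismatch(self, logistic_params):
        with pytest.raises(ValueError, match="dimension"):
            simulate_lv_ode(logistic_params, [1.0, 2.0], SimulationGrid())

    def test_blowup_reports_last_valid_time(self):
        # pure exponential growth with positive feedback explodes
        p = LVParameters(np.array([5.0]), np.array([[5.0]]))
        with pytest.raises(DivergenceError) as exc:
            simulate_lv_ode(p, [1.0], SimulationGrid.over_span(0, 50, 100))
        assert exc.value.last_valid_time is not None
        assert 0 < exc.value.last_valid_time < 50


class TestLVDiscrete:
    def test_hand_euler_step(self, logistic_params):
        grid = SimulationGrid(step=0.1, n_steps=1)
        traj = simulate_lv_discrete(logistic_params, [1.0], grid)
        assert traj.values[-1, 0] == pytest.approx(1.05, abs=1e-12)

    def test_noise_disabled_equals_plain_euler(self, lv_benchmark):
        p, x0 = lv_benchmark.lv_params, lv_benchmark.x0
        grid = SimulationGrid.over_span(0, 5, 40)
        a, B = p.growth_rates, p.interactions
        x = x0.copy()
        expected = [x.copy()]
        for _ in range(grid.n_steps):
            x = x + grid.step * x * (a + B @ x)
            expected.append(x.copy())
        traj = simulate_lv_discrete(p, x0, grid,
                                    noise=NoiseSpec(enabled=False))
        assert np.allclose(traj.values, np.array(expected), rtol=1e-14)

    def test_seeded_noise_reproducible(self, lv_benchmark):
        p, x0, grid = (lv_benchmark.lv_params, lv_benchmark.x0,
                       lv_benchmark.grid)
        noise = NoiseSpec(shape=10_000.0)
        t1 = simulate_lv_discrete(p, x0, grid, noise=noise, seed=5)
        t2 = simulate_lv_discrete(p, x0, grid, noise=noise, seed=5)
        assert np.array_equal(t1.values, t2.values)
        t3 = simulate_lv_discrete(p, x0, grid, noise=noise, seed=6)
        assert not np.array_equal(t1.values, t3.values)

    def test_noise_requires_seed_and_positive_start(self, logistic_params):
        grid = SimulationGrid(step=0.1, n_steps=5)
        with pytest.raises(ValueError, match="seed"):
            simulate_lv_discrete(logistic_params, [1.0], grid,
                                 noise=NoiseSpec())
        with pytest.raises(ValueError, match="positive"):
            simulate_lv_discrete(logistic_params, [0.0], grid,
                                 noise=NoiseSpec(), seed=1)

    def test_euler_error_shrinks_linearly_in_h(self, logistic_params):
        # global Euler error at fixed horizon is O(h) on the logistic
        exact = simulate_lv_ode(logistic_params, [0.1],
                                SimulationGrid(step=4.0, n_steps=1)).values[-1, 0]
        errors = []
        for n in (40, 80, 160):
            grid = SimulationGrid(step=4.0 / n, n_steps=n)
            approx = simulate_lv_discrete(logistic_params, [0.1], grid)
            errors.append(abs(approx.values[-1, 0] - exact))
        ratios = [errors[i] / errors[i + 1] for i in range(2)]
        assert all(1.6 < r < 2.4 for r in ratios)

    def test_positive_noise_keeps_state_nonnegative(self, lv_benchmark):
        traj = simulate_lv_discrete(
            lv_benchmark.lv_params, lv_benchmark.x0, lv_benchmark.grid,
            noise=NoiseSpec(shape=shape_for_noise_sd(0.03)), seed=17)
        assert np.all(traj.values >= 0)

    def test_overshoot_clipped_and_flagged(self):
        # large step drives the Euler increment below zero
        p = LVParameters(np.array([-5.0]), np.array([[-1.0]]))
        grid = SimulationGrid(step=1.0, n_steps=3)
        traj = simulate_lv_discrete(p, [2.0], grid)
        assert traj.clipped_steps
        assert np.all(traj.values >= 0)


class TestProcessNoise:
    def test_draws_positive_and_seeded(self):
        d1 = draw_process_noise(10_000, 1000, 3)
        d2 = draw_process_noise(10_000, 1000, 3)
        assert np.all(d1 > 0)
        assert np.array_equal(d1, d2)

    def test_analytic_mean(self):
        # gamma(k, 1/(k-1)) has mean k/(k-1)
        draws = draw_process_noise(10_000, 200_000, 0)
        assert draws.mean() == pytest.approx(10_000 / 9_999, abs=5e-5)

    def test_shape_must_exceed_one(self):
        with pytest.raises(ValueError):
            draw_process_noise(1.0, 10, 0)
        with pytest.raises(ValueError):
            NoiseSpec(shape=0.5)

    def test_shape_for_sd_inverts_analytic_sd(self):
        for sd in (0.005, 0.01, 0.03):
            k = shape_for_noise_sd(sd)
            assert np.sqrt(k) / (k - 1) == pytest.approx(sd, rel=1e-12)


class TestMARSimulation:
    def test_identity_recursion_fixed(self):
        p = MARParameters(np.zeros(2), np.eye(2))
        traj = simulate_mar(p, [5.0, -2.0], 10, deterministic=True)
        assert np.allclose(traj.values, [5.0, -2.0])

    def test_fixed_point_one_step(self):
        p = MARParameters(np.array([1.0]), np.array([[0.5]]))
        traj = simulate_mar(p, [2.0], 1, deterministic=True)
        assert traj.values[-1, 0] == pytest.approx(2.0)

    def test_seeded_reproducible(self, mar_benchmark):
        p, x0 = mar_benchmark.mar_params, mar_benchmark.x0
        t1 = simulate_mar(p, x0, 30, seed=9)
        t2 = simulate_mar(p, x0, 30, seed=9)
        assert np.array_equal(t1.values, t2.values)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            MARParameters(np.zeros(2), np.zeros((2, 2)),
                          np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSteadyStates:
    def test_logistic_carrying_capacity(self, logistic_params):
        assert lv_steady_state(logistic_params) == pytest.approx([2.0])

    def test_componentwise(self):
        p = LVParameters(np.array([2.0, 2.0]), np.diag([-1.0, -2.0]))
        assert lv_steady_state(p) == pytest.approx([2.0, 1.0])

    def test_singular_interaction_matrix_errors(self):
        p = LVParameters(np.ones(2), np.ones((2, 2)))
        with pytest.raises(SingularMatrixError, match="rank"):
            lv_steady_state(p)

    @pytest.mark.parametrize("beta, alpha, expected", [
        (np.zeros((2, 2)), [3.0, 4.0], [3.0, 4.0]),
        (0.5 * np.eye(2), [1.0, 1.0], [2.0, 2.0]),
    ])
    def test_mar_fixed_points(self, beta, alpha, expected):
        p = MARParameters(np.asarray(alpha), beta)
        assert mar_steady_state(p) == pytest.approx(expected)

    def test_mar_identity_transition_errors(self):
        p = MARParameters(np.ones(2), np.eye(2))
        with pytest.raises(SingularMatrixError):
            mar_steady_state(p)


class TestSteadyStateMap:
    def test_logistic_mapping_rule(self, logistic_params):
        mapped = lv_to_mar_steady_map(logistic_params)
        assert mapped.intercepts == pytest.approx([1.0])
        np.testing.assert_allclose(mapped.transition, [[0.5]])

    def test_zero_interactions_map_to_identity(self):
        p = LVParameters(np.ones(3), np.zeros((3, 3)))
        assert np.array_equal(lv_to_mar_steady_map(p).transition, np.eye(3))

    def test_equivalence_on_random_systems(self):
        # the mapped MAR fixed point equals the LV steady state
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            n = int(rng.integers(1, 6))
            B = rng.uniform(-1, 1, (n, n)) - 1.5 * np.eye(n)
            if abs(np.linalg.det(B)) < 1e-3:
                continue
            p = LVParameters(rng.uniform(0.2, 2.0, n), B)
            lv_ss = lv_steady_state(p)
            mar_ss = mar_steady_state(lv_to_mar_steady_map(p))
            np.testing.assert_allclose(mar_ss, lv_ss, rtol=1e-10)
            checked += 1


class TestTrajectoryInvariants:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(times=[0.0, 0.0, 1.0], values=np.zeros((3, 1)))

    def test_values_must_be_finite(self):
        with pytest.raises(ValueError, match="finite"):
            Trajectory(times=[0.0, 1.0], values=np.array([[1.0], [np.inf]]))
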