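import numpy as np
import pytest
import scipy.linalg

from netctrl import (
    ControlTask,
    OutputProjector,
    StabilizedSystem,
    accuracy_metrics,
    build_projector,
    eigendecompose,
    finite_horizon_gramian,
    laplacian,
    optimal_input,
    rescale_time,
    simulate_trajectory,
    stabilize,
)

from conftest import random_network
from oracles import discretized_control_cost, gramian_quadrature


def scalar_system(a=-1.0):
    return StabilizedSystem(state_matrix=np.array([[a]]), shift=-a, epsilon=0.0)


def scalar_projector():
    return OutputProjector(
        r=1,
        selected_indices=(0,),
        filter_matrix=np.eye(1),
        output_matrix=np.eye(1),
    )


def random_task(seed, n=5, n_drivers=2, r=3, rho=1e-3, epsilon=0.1):
    rng = np.random.default_rng(seed)
    net = random_network(n, seed)
    system = stabilize(net, epsilon=epsilon)
    basis = eigendecompose(laplacian(net))
    xf = rng.normal(1, 2, n)
    proj = build_projector(basis, r, "magnitude", xf)
    return ControlTask(
        system=system,
        drivers=tuple(rng.choice(n, n_drivers, replace=False)),
        projector=proj,
        x0=rng.normal(0, 1, n),
        xf=xf,
        rho=rho,
    )


class TestFiniteHorizonGramian:
    def test_scalar_closed_form(self):
        w = finite_horizon_gramian(np.array([[-1.0]]), np.array([[1.0]]), 1.0)
        assert w[0, 0] == pytest.approx((1 - np.exp(-2)) / 2, rel=1e-12)

    def test_zero_input_matrix(self):
        w = finite_horizon_gramian(-np.eye(3), np.zeros((3, 1)), 2.0)
        np.testing.assert_array_equal(w, 0)

    def test_converges_to_lyapunov_solution(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 4))
        a = -(m @ m.T + np.eye(4))  # well damped, symmetric
        b = rng.normal(size=(4, 2))
        w_inf = scipy.linalg.solve_lyapunov(a, -b @ b.T)
        w = finite_horizon_gramian(a, b, 40.0 / np.min(np.abs(np.linalg.eigvalsh(a))))
        np.testing.assert_allclose(w, w_inf, atol=1e-6 * np.max(np.abs(w_inf)))

    def test_nonsymmetric_van_loan_path(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        a = a - (np.max(np.linalg.eigvals(a).real) + 1.0) * np.eye(4)
        b = rng.normal(size=(4, 1))
        w = finite_horizon_gramian(a, b, 1.5)
        w_quad = gramian_quadrature(a, b, 1.5, n_points=6000)
        np.testing.assert_allclose(w, w_quad, atol=1e-6 * np.max(np.abs(w)))

    def test_symmetric_psd(self):
        net = random_network(8, 2)
        a = stabilize(net, 0.2).state_matrix
        b = np.zeros((8, 2))
        b[[1, 5], [0, 1]] = 1.0
        w = finite_horizon_gramian(a, b, 1.0)
        np.testing.assert_allclose(w, w.T, atol=1e-12)
        assert np.linalg.eigvalsh(w)[0] >= -1e-10


class TestOptimalInput:
    def test_already_at_target_needs_no_input(self):
        task = random_task(3)
        a = task.system.state_matrix
        yf = task.output_matrix @ scipy.linalg.expm(a * task.tf) @ task.x0
        task = ControlTask(
            system=task.system,
            drivers=task.drivers,
            projector=task.projector,
            x0=task.x0,
            xf=task.xf,
            yf=yf,
            rho=task.rho,
        )
        sol = optimal_input(task)
        assert np.max(np.abs(sol.input_signal)) < 1e-10
        assert sol.energy < 1e-20

    def test_scalar_closed_form(self):
        w = (1 - np.exp(-2)) / 2
        rho = 1e-4
        task = ControlTask(
            system=scalar_system(),
            drivers=(0,),
            projector=scalar_projector(),
            x0=np.zeros(1),
            xf=np.ones(1),
            rho=rho,
            dt=0.001,
        )
        sol = optimal_input(task)
        assert sol.output_final[0] == pytest.approx(w / (rho + w), rel=5e-3)
        assert sol.precision == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_discretized_ridge_oracle(self, seed):
        task = random_task(seed)
        sol = optimal_input(task)
        # continuous-time cost of the closed-form solution
        j_oracle = discretized_control_cost(
            task.system.state_matrix,
            task.b_matrix,
            task.output_matrix,
            task.x0,
            task.target_output(),
            task.rho,
            task.tf,
            n_steps=1000,
        )
        # evaluate the closed form's cost continuously (Gramian energy)
        a, c = task.system.state_matrix, task.output_matrix
        w = finite_horizon_gramian(a, task.b_matrix, task.tf)
        g = c @ w @ c.T
        mis = task.target_output() - c @ scipy.linalg.expm(a * task.tf) @ task.x0
        alpha = np.linalg.solve(task.rho * np.eye(c.shape[0]) + g, mis)
        j_closed = float((mis - g @ alpha) @ (mis - g @ alpha) + task.rho * alpha @ g @ alpha)
        assert j_closed == pytest.approx(j_oracle, rel=1e-4)

    def test_optimality_against_perturbations(self):
        # fine grid so the discretization bias is far below the perturbation
        # curvature, making the cost comparison meaningful
        task = random_task(11)
        task = ControlTask(
            system=task.system,
            drivers=task.drivers,
            projector=task.projector,
            x0=task.x0,
            xf=task.xf,
            rho=task.rho,
            dt=0.001,
        )
        sol = optimal_input(task)
        rng = np.random.default_rng(0)
        scale = max(np.max(np.abs(sol.input_signal)), 1.0)

        def discrete_cost(u):
            traj, _ = simulate_trajectory(
                task.system.state_matrix, task.drivers, u, task.x0, task.dt
            )
            y = task.output_matrix @ traj[:, -1]
            energy = np.sum(u[:, :-1] ** 2) * task.dt
            return float(np.sum((task.target_output() - y) ** 2) + task.rho * energy)

        j_star = discrete_cost(sol.input_signal)
        for _ in range(50):
            perturbed = sol.input_signal + rng.normal(0, 0.1 * scale, sol.input_signal.shape)
            assert discrete_cost(perturbed) >= j_star

    def test_rho_monotonicity(self):
        base = random_task(21)
        energies, errors = [], []
        for rho in [1e-5, 1e-4, 1e-3, 1e-2, 1e-1]:
            task = ControlTask(
                system=base.system,
                drivers=base.drivers,
                projector=base.projector,
                x0=base.x0,
                xf=base.xf,
                rho=rho,
            )
            sol = optimal_input(task)
            energies.append(sol.energy)
            errors.append(np.linalg.norm(task.target_output() - sol.output_final))
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(errors, errors[1:]))

    def test_full_actuation_reaches_target(self):
        net = random_network(6, 5)
        basis = eigendecompose(laplacian(net))
        xf = np.random.default_rng(5).normal(1, 2, 6)
        task = ControlTask(
            system=stabilize(net, 0.1),
            drivers=tuple(range(6)),
            projector=build_projector(basis, 6, "magnitude", xf),
            x0=np.zeros(6),
            xf=xf,
            rho=1e-8,
            dt=0.001,
        )
        sol = optimal_input(task)
        assert sol.precision > 0.999

    def test_validation(self):
        task = random_task(1)
        with pytest.raises(ValueError):
            ControlTask(
                system=task.system,
                drivers=(),
                projector=task.projector,
                x0=task.x0,
                xf=task.xf,
            )
        with pytest.raises(ValueError):
            ControlTask(
                system=task.system,
                drivers=task.drivers,
                projector=task.projector,
                x0=task.x0,
                xf=task.xf,
                rho=0.0,
            )


class TestSimulateTrajectory:
    def test_zero_input_zero_state(self):
        traj, flag = simulate_trajectory(-np.eye(3), [0], np.zeros((1, 101)), np.zeros(3), 0.01)
        np.testing.assert_array_equal(traj, 0)
        assert not flag

    def test_scalar_decay_matches_exact(self):
        traj, _ = simulate_trajectory(
            np.array([[-1.0]]), [0], np.zeros((1, 101)), np.ones(1), 0.01
        )
        assert traj[0, -1] == pytest.approx(np.exp(-1), abs=5e-3)

    def test_euler_first_order_convergence(self):
        a = np.array([[-2.0, 1.0], [1.0, -3.0]])
        x0 = np.array([1.0, -1.0])
        exact = scipy.linalg.expm(a) @ x0
        errs = []
        for steps in (100, 200, 400):
            traj, _ = simulate_trajectory(a, [0], np.zeros((1, steps + 1)), x0, 1.0 / steps)
            errs.append(np.linalg.norm(traj[:, -1] - exact))
        rates = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(1.5 < rate < 2.5 for rate in rates)  # observed order ~1

    def test_unstable_dt_flagged(self):
        with pytest.warns(UserWarning, match="stability"):
            traj, flag = simulate_trajectory(
                np.array([[-300.0]]), [0], np.zeros((1, 11)), np.ones(1), 0.01
            )
        assert flag

    def test_divergence_reports_step(self):
        with pytest.warns(UserWarning):
            with pytest.raises(FloatingPointError, match="step"):
                simulate_trajectory(
                    np.array([[-1e6]]), [0], np.zeros((1, 201)), np.ones(1), 0.01
                )


class TestAccuracyMetrics:
    def test_perfect_and_orthogonal(self):
        y = np.array([1.0, 2.0])
        delta, _, _ = accuracy_metrics(y, y, y, y, np.zeros((1, 2)), 0.01)
        assert delta == pytest.approx(1.0)
        delta_perp, _, _ = accuracy_metrics(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), y, y, np.zeros((1, 2)), 0.01
        )
        assert delta_perp == pytest.approx(0.0)

    def test_unit_input_energy(self):
        u = np.ones((1, 101))
        _, _, energy = accuracy_metrics(np.ones(1), np.ones(1), np.ones(1), np.ones(1), u, 0.01)
        assert energy == pytest.approx(1.0)

    def test_zero_target_reported_missing(self):
        delta, eta, _ = accuracy_metrics(
            np.ones(2), np.zeros(2), np.ones(2), np.zeros(2), np.zeros((1, 2)), 0.01
        )
        assert delta is None and eta is None


class TestRescaleTime:
    def test_identity_dynamics(self):
        scaled = rescale_time(-np.eye(3), 0.0102)
        assert np.min(np.linalg.eigvalsh(scaled)) == pytest.approx(-1 / 0.0102, rel=1e-10)
        np.testing.assert_allclose(scaled, -np.eye(3) / 0.0102)

    def test_random_stable_system(self):
        net = random_network(10, 8)
        a = stabilize(net, 0.3).state_matrix
        scaled = rescale_time(a, 0.0102)
        assert np.min(np.linalg.eigvalsh(scaled)) == pytest.approx(-1 / 0.0102, rel=1e-8)
        # eigenvectors unchanged: A~ is a positive scalar multiple of A
        v_a = np.linalg.eigh(a)[1]
        v_s = np.linalg.eigh(scaled)[1]
        np.testing.assert_allclose(np.abs(v_a), np.abs(v_s), atol=1e-8)

    def test_rejects_unstable(self):
        with pytest.raises(ValueError):
            rescale_time(np.eye(2), 0.0102)
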