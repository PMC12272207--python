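"""Optimal control energy: BVP oracle, scaling, conservation, invariances."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp, solve_ivp
from scipy.interpolate import CubicSpline

from enct import (
    ControlTask,
    NodeConnectome,
    decompose_energy_by_pairs,
    edge_network_from_connectome,
    network_activation_energy,
    solve_optimal_control,
    stabilize_continuous,
)


def bvp_oracle_energy(A, x0, xT, T=1.0, rho=1.0):
    """Independent dense boundary-value integration of the state/costate ODE."""
    M = A.shape[0]
    x0 = np.asarray(x0, float)
    xT = np.asarray(xT, float)

    def rhs(t, z):
        x, p = z[:M], z[M:]
        dx = A @ x - p / (2 * rho)
        dp = -2 * x - A.T @ p + 2 * xT[:, None]
        return np.vstack([dx, dp])

    def bc(za, zb):
        return np.concatenate([za[:M] - x0, zb[:M] - xT])

    t = np.linspace(0, T, 101)
    sol = solve_bvp(rhs, bc, t, np.zeros((2 * M, t.size)), tol=1e-10,
                    max_nodes=200_000)
    assert sol.success, sol.message
    tt = np.linspace(0, T, 4001)
    u = -sol.sol(tt)[M:] / (2 * rho)
    return float(np.trapezoid((u**2).sum(axis=0), tt))


def ring_line_graph_network():
    A = np.zeros((6, 6))
    for i in range(6):
        A[i, (i + 1) % 6] = A[(i + 1) % 6, i] = 1.0
    return edge_network_from_connectome(NodeConnectome(A))


class TestSolveOptimalControl:
    def test_zero_target_zero_energy(self):
        task = ControlTask(np.array([[-0.5]]), x0=[0.0], xT=[0.0])
        res = solve_optimal_control(task)
        assert res.total_energy == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(res.input_trajectory, 0.0)

    def test_quadratic_target_scaling(self):
        A = stabilize_continuous(np.array([[0.0, 1.0], [1.0, 0.0]]))[0]
        e1 = solve_optimal_control(
            ControlTask(A, x0=[0.0, 0.0], xT=[1.0, 0.5])
        ).total_energy
        e2 = solve_optimal_control(
            ControlTask(A, x0=[0.0, 0.0], xT=[2.0, 1.0])
        ).total_energy
        assert e2 / e1 == pytest.approx(4.0, rel=1e-6)

    def test_scalar_system_matches_bvp_oracle(self):
        res = solve_optimal_control(
            ControlTask(np.array([[-1.0]]), x0=[0.0], xT=[1.0])
        )
        oracle = bvp_oracle_energy(np.array([[-1.0]]), [0.0], [1.0])
        assert res.total_energy == pytest.approx(oracle, rel=1e-6)
        assert res.terminal_error_rel < 1e-4

    def test_six_element_ring_matches_bvp_oracle(self):
        net = ring_line_graph_network()
        res, norm = network_activation_energy(net, [0])
        A_stab, _ = stabilize_continuous(net.edge_adjacency)
        xT = np.zeros(6)
        xT[0] = 1.0
        oracle = bvp_oracle_energy(A_stab, np.zeros(6), xT)
        assert res.total_energy == pytest.approx(oracle, rel=1e-6)
        assert norm == pytest.approx(res.total_energy)

    def test_forward_resimulation_reproduces_trajectory(self):
        """Integrating x' = Ax + Bu with the returned u reproduces the state
        trajectory and hits the target within 1e-4 relative."""
        A = stabilize_continuous(
            np.array([[0.0, 1.0, 0.5], [1.0, 0.0, 0.2], [0.5, 0.2, 0.0]])
        )[0]
        task = ControlTask(A, x0=[0.0, 0.0, 0.0], xT=[1.0, 0.0, 1.0])
        res = solve_optimal_control(task)
        u_of_t = CubicSpline(res.times, res.input_trajectory, axis=0)
        sol = solve_ivp(
            lambda t, x: A @ x + u_of_t(t),
            (0.0, task.horizon),
            task.x0,
            t_eval=res.times,
            rtol=1e-10,
            atol=1e-12,
        )
        assert np.abs(sol.y.T - res.state_trajectory).max() < 1e-7
        term = np.linalg.norm(sol.y[:, -1] - task.xT) / np.linalg.norm(task.xT)
        assert term <= 1e-4

    def test_energy_nonincreasing_in_rho(self):
        A = stabilize_continuous(np.array([[0.0, 0.8], [0.8, 0.0]]))[0]
        energies = [
            solve_optimal_control(
                ControlTask(A, x0=[0.0, 0.0], xT=[1.0, 1.0], rho=rho)
            ).total_energy
            for rho in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        S = rng.standard_normal((5, 5))
        A = stabilize_continuous(S + S.T)[0]
        xT = rng.standard_normal(5)
        res = solve_optimal_control(ControlTask(A, x0=np.zeros(5), xT=xT))
        perm = rng.permutation(5)
        res_p = solve_optimal_control(
            ControlTask(A[np.ix_(perm, perm)], x0=np.zeros(5), xT=xT[perm])
        )
        assert res_p.total_energy == pytest.approx(res.total_energy, rel=1e-9)
        assert np.allclose(res_p.element_energy, res.element_energy[perm],
                           rtol=1e-8, atol=1e-12)

    def test_control_mask_restricts_input(self):
        A = stabilize_continuous(np.array([[0.0, 1.0], [1.0, 0.0]]))[0]
        mask = np.array([True, False])
        res = solve_optimal_control(
            ControlTask(A, x0=[0.0, 0.0], xT=[0.5, 0.5], control_mask=mask)
        )
        assert np.allclose(res.input_trajectory[:, 1], 0.0)
        assert res.element_energy[1] == 0.0
        assert res.terminal_error_rel < 1e-4


class TestNetworkActivationEnergy:
    def test_empty_target_is_zero_with_warning(self, triangle):
        net = edge_network_from_connectome(triangle)
        with pytest.warns(RuntimeWarning, match="empty target"):
            res, norm = network_activation_energy(net, [])
        assert res.total_energy == 0.0 and norm == 0.0

    def test_symmetric_targets_equal_energy(self, triangle):
        """The triangle's line graph is vertex-transitive: activating any
        single edge costs the same."""
        net = edge_network_from_connectome(triangle)
        energies = [
            network_activation_energy(net, [k])[0].total_energy for k in range(3)
        ]
        assert np.allclose(energies, energies[0], rtol=1e-9)

    def test_target_out_of_range_rejected(self, triangle):
        net = edge_network_from_connectome(triangle)
        with pytest.raises(ValueError, match="out of range"):
            network_activation_energy(net, [7])

    def test_normalization_divides_by_target_count(self):
        net = ring_line_graph_network()
        res, norm = network_activation_energy(net, [0, 2, 4])
        assert norm == pytest.approx(res.total_energy / 3)


class TestDecomposeEnergy:
    def _result(self, energies):
        from enct.energy import EnergyResult

        e = np.asarray(energies, float)
        return EnergyResult(
            times=np.zeros(2),
            input_trajectory=np.zeros((2, len(e))),
            state_trajectory=np.zeros((2, len(e))),
            costate_trajectory=np.zeros((2, len(e))),
            element_energy=e,
            total_energy=float(e.sum()),
            terminal_error=0.0,
            terminal_error_rel=0.0,
        )

    def test_single_label_gets_total(self):
        res = self._result([1.0, 2.0, 3.0])
        table = decompose_energy_by_pairs(res, ["DM-DM"] * 3)
        assert table["DM-DM"] == pytest.approx(6.0)

    def test_two_label_manual_grouping_and_conservation(self):
        res = self._result([1.0, 2.0, 4.0, 8.0])
        table = decompose_energy_by_pairs(res, ["FP-FP", "DM-FP", "FP-FP", "DM-FP"])
        assert table["FP-FP"] == pytest.approx(5.0)
        assert table["DM-FP"] == pytest.approx(10.0)
        assert table.sum() == pytest.approx(res.total_energy, abs=1e-12)

    def test_unlabeled_edge_rejected(self):
        res = self._result([1.0, 2.0])
        with pytest.raises(ValueError, match="cover all edges"):
            decompose_energy_by_pairs(res, ["FP-FP"])
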