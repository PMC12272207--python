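"""Average and modal controllability of discrete linear network systems.

The network (node adjacency A or edge adjacency A_E) is treated as the
system matrix of the discrete linear model x(t+1) = A x(t) + B_K u_K(t).
Before any controllability computation the matrix is rescaled by
1/(1 + |lambda|_max) so the system is Schur-stable and the infinite-horizon
controllability Gramian

    W_K = sum_{tau=0..inf} A^tau B_K B_K^T A^tau

converges.  Average controllability of element k is Trace(W_k) for the
single-input matrix B = e_k; modal controllability is

    phi_k = sum_j (1 - lambda_j^2) v_kj^2

over the orthonormal eigenmodes (lambda_j, v_j) of the stabilized matrix.
High average controllability marks elements that cheaply steer the system
to nearby states; high modal controllability marks elements that can reach
distant, weakly coupled modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .line_graph import EdgeNetwork
from .connectome import NodeConnectome
from .line_graph import edge_network_from_connectome

__all__ = [
    "LinearSystem",
    "ControllabilityProfile",
    "stabilize",
    "average_controllability",
    "average_controllability_all",
    "modal_controllability",
    "edge_controllability",
    "node_controllability",
]

_SYM_ATOL = 1e-8


def _check_symmetric(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=_SYM_ATOL, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


@dataclass
class LinearSystem:
    """Stabilized discrete linear system with a designated control set."""

    system_matrix: np.ndarray
    control_mask: np.ndarray | None = None  # bool mask of controlled elements

    def __post_init__(self) -> None:
        self.system_matrix = _check_symmetric(self.system_matrix, "system_matrix")
        if self.control_mask is not None:
            self.control_mask = np.asarray(self.control_mask, dtype=bool)

    @property
    def M(self) -> int:
        return self.system_matrix.shape[0]

    def spectral_radius(self) -> float:
        if self.M == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvalsh(self.system_matrix))))


@dataclass
class ControllabilityProfile:
    """Per-element average (ac) and modal (mc) controllability values."""

    ac: np.ndarray
    mc: np.ndarray
    eigenvalues: np.ndarray
    stabilization_factor: float
    level: str = "node"  # "node" | "edge"
    edge_list: object | None = field(default=None, repr=False)


def stabilize(raw_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale a symmetric matrix by 1/(1 + |lambda|_max).

    Returns the stabilized matrix and the factor 1 + |lambda|_max.  The
    output spectral radius is strictly below 1 for any symmetric input,
    which guarantees Gramian convergence.
    """
    M = _check_symmetric(raw_matrix, "raw_matrix")
    if M.size == 0:
        return M, 1.0
    radius = float(np.max(np.abs(np.linalg.eigvalsh(M))))
    factor = 1.0 + radius
    return M / factor, factor


def average_controllability(system: LinearSystem, element: int) -> float:
    """Trace of the single-input controllability Gramian for one element.

    The Gramian solves the discrete Lyapunov equation
    W - A W A^T = B B^T with B = e_element; Trace(W) >= 1 always because
    the tau=0 term contributes e_k e_k^T.
    """
    A = system.system_matrix
    rho = system.spectral_radius()
    if rho >= 1.0:
        raise ValueError(
            f"system is not Schur-stable (spectral radius {rho:.6g} >= 1); "
            "stabilize the matrix first"
        )
    M = A.shape[0]
    if not 0 <= element < M:
        raise ValueError(f"element {element} out of range for system size {M}")
    Q = np.zeros((M, M))
    Q[element, element] = 1.0
    W = scipy.linalg.solve_discrete_lyapunov(A, Q)
    return float(np.trace(W))


def average_controllability_all(system_matrix: np.ndarray) -> np.ndarray:
    """Average controllability of every element in one eigendecomposition.

    For symmetric Schur-stable A, Trace(W_k) = [(I - A^2)^(-1)]_kk, so the
    whole profile is the diagonal of (I - A^2)^(-1):  sum_j v_kj^2 / (1 - lambda_j^2).
    Exact (no series truncation) and O(M^3) total instead of O(M^4).
    """
    A = _check_symmetric(system_matrix, "system_matrix")
    lam, V = np.linalg.eigh(A)
    if np.max(np.abs(lam), initial=0.0) >= 1.0:
        raise ValueError(
            "system is not Schur-stable (spectral radius "
            f"{np.max(np.abs(lam)):.6g} >= 1); stabilize the matrix first"
        )
    return (V**2 / (1.0 - lam**2)).sum(axis=1)


def modal_controllability(system_matrix: np.ndarray) -> np.ndarray:
    """phi_k = sum_j (1 - lambda_j^2) v_kj^2 over orthonormal eigenmodes.

    After 1/(1 + |lambda|_max) stabilization each phi lies in [0, 1], and
    sum_k phi_k = M - sum_j lambda_j^2 by eigenvector orthonormality.  For
    degenerate eigenvalues any orthonormal eigenbasis gives the same phi.
    """
    A = _check_symmetric(system_matrix, "system_matrix")
    lam, V = np.linalg.eigh(A)
    return ((1.0 - lam**2) * V**2).sum(axis=1)


def _profile(raw: np.ndarray, level: str, edge_list=None) -> ControllabilityProfile:
    A_norm, factor = stabilize(raw)
    lam = np.linalg.eigvalsh(A_norm) if A_norm.size else np.array([])
    return ControllabilityProfile(
        ac=average_controllability_all(A_norm) if A_norm.size else np.array([]),
        mc=modal_controllability(A_norm) if A_norm.size else np.array([]),
        eigenvalues=lam,
        stabilization_factor=factor,
        level=level,
        edge_list=edge_list,
    )


def edge_controllability(edge_network: EdgeNetwork) -> ControllabilityProfile:
    """eAC and eMC for every edge of an edge-centric network.

    Stabilizes A_E once; each edge is evaluated as a single control input
    (B is L x 1), matching the per-element Lyapunov route exactly.
    """
    return _profile(
        edge_network.edge_adjacency, level="edge", edge_list=edge_network.edge_list
    )


def node_controllability(connectome: NodeConnectome) -> ControllabilityProfile:
    """Node-level AC and MC on the (stabilized) node adjacency matrix."""
    return _profile(connectome.adjacency, level="node")


def edge_controllability_from_connectome(
    connectome: NodeConnectome,
) -> ControllabilityProfile:
    """Convenience: line-graph transform followed by edge controllability."""
    return edge_controllability(edge_network_from_connectome(connectome))
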