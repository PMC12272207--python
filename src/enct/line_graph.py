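"""Node-to-edge (line-graph) transform of weighted connectomes.

A node-centric graph G with adjacency A is lifted to an edge-centric
network L(G) through its weighted incidence matrix C, which satisfies

    C C^T = A + D,

where D is the diagonal strength matrix.  Each column of C corresponds to
one edge alpha = (i, j) and carries sqrt(w_alpha) in rows i and j.  The
edge adjacency matrix is then

    A_E[alpha, beta] = sum_i C[i, alpha] C[i, beta]   for alpha != beta,

i.e., sqrt(w_alpha w_beta) when the two edges share exactly one endpoint
and 0 otherwise; the diagonal is 0 by convention so that A_E is a plain
weighted adjacency over edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import NodeConnectome

__all__ = [
    "EdgeList",
    "IncidenceMatrix",
    "EdgeNetwork",
    "build_edge_list",
    "build_incidence",
    "build_edge_adjacency",
    "edge_network_from_connectome",
    "n_edge_features",
    "align_edge_values",
]


@dataclass
class EdgeList:
    """Canonical (row-major upper-triangular) ordered list of weighted edges."""

    edges: np.ndarray  # (L, 2) int, i < j
    weights: np.ndarray  # (L,) positive
    n_nodes: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if len(self.edges) and (
            self.edges.min() < 0 or self.edges.max() >= self.n_nodes
        ):
            raise ValueError("edge index out of range")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j")

    @property
    def L(self) -> int:
        return len(self.weights)

    def pairs(self) -> list[tuple[int, int]]:
        return [tuple(e) for e in self.edges]


@dataclass
class IncidenceMatrix:
    """N x L weighted incidence matrix C with C C^T = A + D."""

    C: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    @property
    def L(self) -> int:
        return self.C.shape[1]


@dataclass
class EdgeNetwork:
    """Edge-centric (line-graph) network derived from a node connectome."""

    edge_adjacency: np.ndarray  # (L, L), symmetric, zero diagonal
    edge_weights: np.ndarray  # (L,), diagonal of W
    edge_list: EdgeList
    source: NodeConnectome | None = None

    @property
    def L(self) -> int:
        return len(self.edge_weights)


def build_edge_list(connectome: NodeConnectome) -> EdgeList:
    """Enumerate suprathreshold edges in row-major upper-triangular order."""
    A = connectome.adjacency
    iu, ju = np.triu_indices(connectome.n_nodes, k=1)
    w = A[iu, ju]
    keep = (w >= connectome.absence_threshold) & (w > 0)
    return EdgeList(
        edges=np.column_stack([iu[keep], ju[keep]]),
        weights=w[keep],
        n_nodes=connectome.n_nodes,
    )


def build_incidence(edge_list: EdgeList, n_nodes: int | None = None) -> IncidenceMatrix:
    """Weighted incidence matrix: column alpha has sqrt(w_alpha) at both endpoints."""
    n = edge_list.n_nodes if n_nodes is None else n_nodes
    if len(edge_list.edges) and edge_list.edges.max() >= n:
        raise ValueError("edge index out of range for n_nodes")
    C = np.zeros((n, edge_list.L))
    sw = np.sqrt(edge_list.weights)
    cols = np.arange(edge_list.L)
    C[edge_list.edges[:, 0], cols] = sw
    C[edge_list.edges[:, 1], cols] = sw
    return IncidenceMatrix(C=C)


def build_edge_adjacency(
    incidence: IncidenceMatrix,
    edge_list: EdgeList,
    source: NodeConnectome | None = None,
) -> EdgeNetwork:
    """Edge adjacency A_E = C^T C off the diagonal; diagonal forced to zero."""
    if incidence.L != edge_list.L:
        raise ValueError("incidence and edge list dimensions are inconsistent")
    A_E = incidence.C.T @ incidence.C
    np.fill_diagonal(A_E, 0.0)
    A_E = 0.5 * (A_E + A_E.T)
    return EdgeNetwork(
        edge_adjacency=A_E,
        edge_weights=edge_list.weights.copy(),
        edge_list=edge_list,
        source=source,
    )


def edge_network_from_connectome(connectome: NodeConnectome) -> EdgeNetwork:
    """Full node-to-edge transform: edge list, incidence, edge adjacency."""
    el = build_edge_list(connectome)
    return build_edge_adjacency(build_incidence(el), el, source=connectome)


def n_edge_features(n_nodes: int) -> int:
    """Number of aligned edge features: all N(N-1)/2 node pairs."""
    return n_nodes * (n_nodes - 1) // 2


def align_edge_values(
    values: np.ndarray,
    edge_list: EdgeList,
    n_nodes: int | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Scatter per-edge values into the full upper-triangle feature vector.

    Cross-subject analyses require feature vectors of identical length even
    though each subject realizes a different edge support.  The canonical
    layout is the row-major upper triangle over all node pairs; pairs with
    no edge in this subject receive ``fill`` (0 by default, ``np.nan`` for
    a missing-value convention).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != edge_list.L:
        raise ValueError("values length does not match edge list")
    n = edge_list.n_nodes if n_nodes is None else n_nodes
    out = np.full(n_edge_features(n), fill, dtype=float)
    i, j = edge_list.edges[:, 0], edge_list.edges[:, 1]
    # row-major upper-triangle linear index of pair (i, j), i < j
    flat = (i * (2 * n - i - 1)) // 2 + (j - i - 1)
    out[flat] = values
    return out
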