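"""Node-level structural connectome container and validation.

A structural connectome is a weighted, undirected graph over parcellated
gray-matter regions; edge weights are nonnegative fiber-strength values
(e.g., quantitative anisotropy averaged along streamlines).  Weights below
a small absence threshold are artifacts of the tractography pipeline and
are treated as "no connection".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Weights strictly below this are considered numerically spurious and zeroed.
DEFAULT_ABSENCE_THRESHOLD = 1e-3

SYMMETRY_ATOL = 1e-8


@dataclass
class NodeConnectome:
    """Weighted symmetric node-level adjacency matrix with metadata.

    Parameters
    ----------
    adjacency
        N x N symmetric nonnegative matrix with zero diagonal.  Entries in
        (0, ``absence_threshold``) are zeroed on construction.
    node_labels
        Optional region names; defaults to ``"n000", "n001", ...``.
    absence_threshold
        Minimum weight considered a real connection.
    """

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if not np.allclose(A, A.T, atol=SYMMETRY_ATOL, rtol=0.0):
            raise ValueError("adjacency must be symmetric (tolerance 1e-8)")
        neg = np.argwhere(A < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(f"negative weight at cell ({i}, {j}): {A[i, j]!r}")
        A = 0.5 * (A + A.T)  # exact symmetry
        np.fill_diagonal(A, 0.0)
        A[A < self.absence_threshold] = 0.0
        self.adjacency = A
        if not self.node_labels:
            self.node_labels = [f"n{i:03d}" for i in range(A.shape[0])]
        if len(self.node_labels) != A.shape[0]:
            raise ValueError("node_labels length does not match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def strength(self) -> np.ndarray:
        """Weighted nodal strength d_i = sum_j A_ij (diagonal of the degree matrix)."""
        return self.adjacency.sum(axis=1)

    @property
    def degree(self) -> np.ndarray:
        """Binary degree (number of suprathreshold connections per node)."""
        return (self.adjacency > 0).sum(axis=1)

    def degree_matrix(self) -> np.ndarray:
        """Diagonal strength matrix D with D_ii = sum_j A_ij."""
        return np.diag(self.strength)
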