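"""Aggregation of edge-level values to nodes, whole brain, and canonical networks.

Edge controllability and energy live on L edges; downstream comparisons
need them mapped back to nodes (mean over incident edges), summed over the
whole brain, or pooled into the K(K+1)/2 within/between pairs of canonical
resting-state networks (7 networks -> 28 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .line_graph import EdgeList

__all__ = [
    "CanonicalPartition",
    "node_mean_edge_values",
    "whole_brain_sum",
    "aggregate_by_pair",
]


@dataclass
class CanonicalPartition:
    """Assignment of every node to one of K canonical networks."""

    node_to_network: np.ndarray  # length-N array of network labels (strings)

    def __post_init__(self) -> None:
        self.node_to_network = np.asarray(self.node_to_network, dtype=object)
        if self.node_to_network.ndim != 1 or self.node_to_network.size == 0:
            raise ValueError("node_to_network must be a non-empty 1-D label array")
        if any(lab is None or str(lab) == "" for lab in self.node_to_network):
            raise ValueError("every node must carry a network label")

    @property
    def networks(self) -> list[str]:
        return sorted({str(x) for x in self.node_to_network})

    @property
    def K(self) -> int:
        return len(self.networks)

    @property
    def n_pairs(self) -> int:
        """Number of unordered network pairs, K within + K(K-1)/2 between."""
        return self.K * (self.K + 1) // 2

    def pair_label(self, i: int, j: int) -> str:
        a, b = sorted((str(self.node_to_network[i]), str(self.node_to_network[j])))
        return f"{a}-{b}"

    def pair_labels(self, edge_list: EdgeList) -> list[str]:
        """Unordered network-pair label of every edge, in edge-list order."""
        if edge_list.L and edge_list.edges.max() >= len(self.node_to_network):
            raise ValueError("partition does not cover all edge endpoints")
        return [self.pair_label(i, j) for i, j in edge_list.edges]

    @classmethod
    def from_mapping(
        cls, mapping: dict[str, str], node_labels: list[str]
    ) -> "CanonicalPartition":
        missing = [lab for lab in node_labels if lab not in mapping]
        if missing:
            raise ValueError(f"unlabeled node(s): {missing[:5]}")
        return cls(np.array([mapping[lab] for lab in node_labels], dtype=object))


def node_mean_edge_values(
    values: np.ndarray, edge_list: EdgeList, n_nodes: int | None = None
) -> np.ndarray:
    """Mean of incident-edge values per node; isolated nodes get NaN.

    This is the node-mean mapping used to compare edge controllability with
    node controllability: sum the value of every edge touching a node and
    divide by that node's edge count.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != edge_list.L:
        raise ValueError("values length does not match edge list")
    n = edge_list.n_nodes if n_nodes is None else n_nodes
    total = np.zeros(n)
    count = np.zeros(n)
    for col in (0, 1):
        np.add.at(total, edge_list.edges[:, col], values)
        np.add.at(count, edge_list.edges[:, col], 1.0)
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


def whole_brain_sum(values: np.ndarray) -> float:
    """Sum of a per-edge quantity over all edges (whole-brain total)."""
    return float(np.sum(np.asarray(values, dtype=float)))


def aggregate_by_pair(
    values: np.ndarray,
    partition: CanonicalPartition,
    edge_list: EdgeList,
    how: str = "sum",
) -> pd.DataFrame:
    """K x K symmetric table of per-edge values pooled by network pair.

    Entry (m, n) pools the values of edges with one endpoint in network m
    and the other in network n; within-network pools sit on the diagonal.
    ``how="sum"`` (default) is conservative — the sum over unordered pairs
    equals the whole-brain sum; ``how="mean"`` divides each cell by its
    edge count (NaN for empty cells).
    """
    if how not in {"sum", "mean"}:
        raise ValueError("how must be 'sum' or 'mean'")
    values = np.asarray(values, dtype=float)
    if len(values) != edge_list.L:
        raise ValueError("values length does not match edge list")
    nets = partition.networks
    idx = {name: k for k, name in enumerate(nets)}
    total = np.zeros((len(nets), len(nets)))
    count = np.zeros((len(nets), len(nets)))
    labels = partition.node_to_network
    for (i, j), v in zip(edge_list.edges, values):
        a, b = idx[str(labels[i])], idx[str(labels[j])]
        total[a, b] += v
        count[a, b] += 1
        if a != b:
            total[b, a] += v
            count[b, a] += 1
    if how == "mean":
        with np.errstate(invalid="ignore"):
            total = total / count
        total[count == 0] = np.nan
    return pd.DataFrame(total, index=nets, columns=nets)
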