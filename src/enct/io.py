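"""Delimited-text readers and writers for connectomes, partitions, and tables.

All on-disk formats are plain text: square numeric matrices (comma or
whitespace delimited, optional label header row/column), two-column
partition files (node label, network label), and subject tables with an ID
column.  Edge lists are written 0-based with a header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import NodeConnectome, DEFAULT_ABSENCE_THRESHOLD
from .line_graph import EdgeList
from .summaries import CanonicalPartition

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_partition",
    "write_partition",
    "write_edge_list",
    "read_edge_list",
    "write_matrix",
    "read_subject_table",
    "write_manifest",
]


def _sniff_sep(path: Path) -> str | None:
    first = Path(path).read_text().splitlines()[0]
    return "," if "," in first else r"\s+"


def read_connectome(
    path: str | Path,
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD,
) -> NodeConnectome:
    """Read a square adjacency matrix, auto-detecting delimiter and labels.

    A non-numeric first row is treated as a header of node labels (with a
    matching first label column).  Validation (symmetry, nonnegativity,
    squareness) happens in :class:`NodeConnectome`.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, engine="python")
    labels: list[str] = []
    try:
        A = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, engine="python")
        labels = [str(x) for x in df.index]
        A = df.to_numpy(dtype=float)
    return NodeConnectome(A, labels, absence_threshold)


def write_connectome(
    connectome: NodeConnectome, path: str | Path, labels: bool = False
) -> None:
    path = Path(path)
    if labels:
        pd.DataFrame(
            connectome.adjacency,
            index=connectome.node_labels,
            columns=connectome.node_labels,
        ).to_csv(path)
    else:
        np.savetxt(path, connectome.adjacency, delimiter=",")


def read_partition(path: str | Path) -> dict[str, str]:
    """Two-column (node label, network label) file -> mapping."""
    df = pd.read_csv(Path(path), sep=None, header=None, engine="python",
                     comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"partition file must have 2 columns, got {df.shape[1]}")
    return dict(zip(df[0], df[1]))


def write_partition(partition: CanonicalPartition, node_labels: list[str],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab, net in zip(node_labels, partition.node_to_network):
            fh.write(f"{lab}\t{net}\n")


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for (i, j), w in zip(edge_list.edges, edge_list.weights):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")


def read_edge_list(path: str | Path, n_nodes: int) -> EdgeList:
    df = pd.read_csv(Path(path), sep="\t")
    return EdgeList(
        edges=df[["node_i", "node_j"]].to_numpy(int),
        weights=df["weight"].to_numpy(float),
        n_nodes=n_nodes,
    )


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(matrix), delimiter=",")


def read_subject_table(path: str | Path, id_column: str | None = None) -> pd.DataFrame:
    """Delimited subject table indexed by its (string) subject-ID column."""
    df = pd.read_csv(Path(path), sep=None, engine="python")
    col = id_column if id_column is not None else df.columns[0]
    df[col] = df[col].astype(str)
    return df.set_index(col)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
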