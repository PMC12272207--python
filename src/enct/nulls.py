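"""Rewired null connectomes and nonparametric inference.

The null preserves, per draw: the binary degree sequence exactly (topology
randomized by Maslov–Sneppen double-edge swaps), the weight multiset
exactly (weights are permuted, never altered), and the nodal strength
sequence approximately (weights are reassigned to the rewired topology by
rank-matching the original strength profile).  Comparing an empirical
statistic against an ensemble of such nulls yields nonparametric p-values;
Benjamini–Hochberg FDR handles multiplicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectome import NodeConnectome
from .line_graph import build_edge_list

__all__ = ["NullEnsemble", "rewire_null", "null_pvalues", "fdr_bh",
           "pvalues_from_ensemble"]

log = logging.getLogger(__name__)

DEFAULT_N_NULLS = 5000
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class NullEnsemble:
    """Null-distribution summary for a vector-valued network statistic."""

    n_nulls: int
    null_values: np.ndarray  # (n_nulls, M)
    empirical_values: np.ndarray  # (M,)
    p_values: np.ndarray  # (M,)
    side: str
    seed: int
    n_failed: int = 0


def _rank_match_weights(
    edges: np.ndarray, weights: np.ndarray, strength: np.ndarray
) -> np.ndarray:
    """Permute the weight multiset onto edges to approximate a target
    strength sequence.

    Weights are placed largest-first: each goes to the unassigned edge
    whose endpoints have the largest product of *residual* (not yet
    consumed) target strengths, and the residuals are decremented after
    every placement.  This is the sequential rank-matching step of the
    standard weighted rewiring null.
    """
    L = len(weights)
    w_desc = np.sort(weights)[::-1]
    out = np.zeros(L)
    unassigned = np.ones(L, dtype=bool)
    s_res = strength.astype(float).copy()
    for pos in range(L):
        idx = np.flatnonzero(unassigned)
        score = s_res[edges[idx, 0]] * s_res[edges[idx, 1]]
        j = idx[np.argmax(score)]
        out[j] = w_desc[pos]
        unassigned[j] = False
        s_res[edges[j, 0]] -= w_desc[pos]
        s_res[edges[j, 1]] -= w_desc[pos]
    return out


def rewire_null(
    connectome: NodeConnectome,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
) -> NodeConnectome:
    """One degree-, weight-, and (approximately) strength-preserving null.

    Double-edge swaps randomize topology at fixed degree sequence; the
    original weight multiset is then rank-matched onto the new topology
    using the original nodal strengths, which keeps nulls' strengths
    strongly correlated with the empirical ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    el = build_edge_list(connectome)
    L = el.L
    n = connectome.n_nodes
    if L < 2:
        warnings.warn(
            "graph has fewer than 2 edges; returning a weight-reshuffled copy",
            RuntimeWarning,
            stacklevel=2,
        )
        return NodeConnectome(
            connectome.adjacency.copy(),
            list(connectome.node_labels),
            connectome.absence_threshold,
        )

    edges = [tuple(e) for e in el.edges]
    edge_set = set(edges)
    n_attempts = swaps_per_edge * L
    successes = 0
    for _ in range(n_attempts):
        a_idx, b_idx = rng.integers(0, L, size=2)
        if a_idx == b_idx:
            continue
        (u, v), (x, y) = edges[a_idx], edges[b_idx]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, y) and (x, v)
        e1 = (min(u, y), max(u, y))
        e2 = (min(x, v), max(x, v))
        if u == y or x == v:
            continue
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[a_idx])
        edge_set.discard(edges[b_idx])
        edges[a_idx], edges[b_idx] = e1, e2
        edge_set.add(e1)
        edge_set.add(e2)
        successes += 1
    if successes == 0:
        warnings.warn(
            "no legal double-edge swap found (graph too small or complete); "
            "returning a weight-reshuffled copy",
            RuntimeWarning,
            stacklevel=2,
        )

    new_edges = np.asarray(edges, dtype=int)
    new_w = _rank_match_weights(new_edges, el.weights, connectome.strength)
    A = np.zeros((n, n))
    A[new_edges[:, 0], new_edges[:, 1]] = new_w
    A[new_edges[:, 1], new_edges[:, 0]] = new_w
    return NodeConnectome(
        A, list(connectome.node_labels), connectome.absence_threshold
    )


def pvalues_from_ensemble(
    null_values: np.ndarray, empirical: np.ndarray, side: str
) -> np.ndarray:
    """Nonparametric p with a +1 pseudo-count: p = (1 + #beats) / (1 + n).

    ``side="greater"`` tests whether the empirical value is greater than
    the null (a null >= empirical counts as a beat); ``"less"`` mirrors;
    ``"two-sided"`` doubles the smaller one-sided p, capped at 1.
    """
    null_values = np.atleast_2d(np.asarray(null_values, dtype=float))
    empirical = np.asarray(empirical, dtype=float).reshape(-1)
    n = null_values.shape[0]
    p_greater = (1.0 + (null_values >= empirical).sum(axis=0)) / (1.0 + n)
    p_less = (1.0 + (null_values <= empirical).sum(axis=0)) / (1.0 + n)
    if side == "greater":
        return p_greater
    if side == "less":
        return p_less
    if side == "two-sided":
        return np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    raise ValueError(f"unknown side {side!r}")


def null_pvalues(
    statistic_fn: Callable[[NodeConnectome], np.ndarray],
    connectome: NodeConnectome,
    n_nulls: int = DEFAULT_N_NULLS,
    side: str = "greater",
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> NullEnsemble:
    """Nonparametric p-values of a network statistic against rewired nulls.

    ``statistic_fn`` maps a connectome to a fixed-length vector (a scalar
    is treated as length 1).  Nulls on which the statistic fails are
    dropped with a logged count.
    """
    empirical = np.asarray(statistic_fn(connectome), dtype=float).reshape(-1)
    ss = np.random.SeedSequence(seed)
    rows = []
    n_failed = 0
    for child in ss.spawn(n_nulls):
        rng = np.random.default_rng(child)
        null = rewire_null(connectome, swaps_per_edge=swaps_per_edge, seed=rng)
        try:
            val = np.asarray(statistic_fn(null), dtype=float).reshape(-1)
        except Exception as err:  # noqa: BLE001 — a failed null is dropped, not fatal
            n_failed += 1
            log.warning("statistic failed on a null model (%s); dropping it", err)
            continue
        if val.shape != empirical.shape:
            n_failed += 1
            log.warning("statistic shape mismatch on a null model; dropping it")
            continue
        rows.append(val)
    if n_failed:
        log.info("dropped %d of %d null models", n_failed, n_nulls)
    if not rows:
        raise RuntimeError("statistic failed on every null model")
    null_values = np.vstack(rows)
    p = pvalues_from_ensemble(null_values, empirical, side)
    return NullEnsemble(
        n_nulls=len(rows),
        null_values=null_values,
        empirical_values=empirical,
        p_values=p,
        side=side,
        seed=seed,
        n_failed=n_failed,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up at level q → (reject mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float).reshape(-1)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
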