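"""Synthetic connectomes, cohorts, and phenotypes with known structure.

The generator emulates the gross statistics of tractography-derived
structural connectomes: a sparse symmetric block structure (denser within
canonical networks than between), heavy-tailed positive weights
(log-normal, mimicking the positive skew of quantitative-anisotropy edge
weights), and an absence threshold of 0.001 below which a weight is
treated as no connection.

Cohorts share the group topology; subject variation has two components,
both mean-corrected so the cohort average converges to the group matrix:

* a per-subject global scale factor (log-normal, sd ``subject_scale_sd``)
  modeling individual differences in overall connectome strength, which
  induces realistic positive correlations between edges across subjects;
* independent per-edge log-normal noise (sd ``subject_noise_sd``).

Phenotypes are planted as a linear combination of standardized edge
features plus Gaussian noise scaled to a requested signal R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .connectome import NodeConnectome, DEFAULT_ABSENCE_THRESHOLD
from .line_graph import align_edge_values, build_edge_list
from .summaries import CanonicalPartition

__all__ = [
    "SyntheticSpec",
    "generate_connectome",
    "generate_cohort",
    "generate_phenotype",
    "cohort_edge_features",
    "canonical_partition_for",
]

#: The seven canonical resting-state networks used for network-pair analyses.
CANONICAL_NETWORKS = ("VI", "SM", "DA", "VA", "LM", "FP", "DM")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic connectome generator.

    Defaults emulate a 120-region whole-brain parcellation partitioned into
    the 7 canonical networks, with within-network density 0.35, between
    0.15, and log-normal weights exp(N(-2.5, 0.8^2)) (median ~0.08,
    heavy right tail).
    """

    n_nodes: int = 120
    n_networks: int = 7
    within_density: float = 0.35
    between_density: float = 0.15
    weight_log_mean: float = -2.5
    weight_log_sd: float = 0.8
    subject_noise_sd: float = 0.2
    subject_scale_sd: float = 0.1
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_density", "between_density"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name}={d} is not a density in [0, 1]")
        if self.n_nodes < 2 or self.n_networks < 1:
            raise ValueError("need n_nodes >= 2 and n_networks >= 1")
        if self.n_networks > self.n_nodes:
            raise ValueError("more networks than nodes")

    def to_dict(self) -> dict:
        return asdict(self)


def _block_assignment(spec: SyntheticSpec) -> np.ndarray:
    """Contiguous, near-equal-sized network blocks over the nodes."""
    return np.array(
        [
            CANONICAL_NETWORKS[b % len(CANONICAL_NETWORKS)]
            if spec.n_networks <= len(CANONICAL_NETWORKS)
            else f"net{b:02d}"
            for b in (np.arange(spec.n_nodes) * spec.n_networks // spec.n_nodes)
        ],
        dtype=object,
    )


def canonical_partition_for(spec: SyntheticSpec) -> CanonicalPartition:
    """The partition matching ``generate_connectome``'s block structure."""
    return CanonicalPartition(_block_assignment(spec))


def generate_connectome(spec: SyntheticSpec) -> NodeConnectome:
    """One block-structured sparse weighted symmetric connectome."""
    rng = np.random.default_rng(spec.seed)
    blocks = np.arange(spec.n_nodes) * spec.n_networks // spec.n_nodes
    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    same = blocks[iu] == blocks[ju]
    dens = np.where(same, spec.within_density, spec.between_density)
    present = rng.random(len(iu)) < dens
    w = np.zeros(len(iu))
    w[present] = np.exp(
        spec.weight_log_mean + spec.weight_log_sd * rng.standard_normal(present.sum())
    )
    A = np.zeros((spec.n_nodes, spec.n_nodes))
    A[iu, ju] = w
    A[ju, iu] = w
    return NodeConnectome(
        A,
        node_labels=[f"n{i:03d}" for i in range(spec.n_nodes)],
        absence_threshold=spec.absence_threshold,
    )


def generate_cohort(spec: SyntheticSpec, n_subjects: int) -> list[NodeConnectome]:
    """Cohort of subjects sharing the group topology.

    Subject weights are w * g_s * e_{edge,s} with mean-one log-normal
    factors, so E[subject matrix] equals the group matrix and the cohort
    mean converges to it as n grows.
    """
    group = generate_connectome(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, n_subjects]))
    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    w = group.adjacency[iu, ju]
    subjects = []
    for _ in range(n_subjects):
        g = np.exp(
            spec.subject_scale_sd * rng.standard_normal()
            - 0.5 * spec.subject_scale_sd**2
        )
        e = np.exp(
            spec.subject_noise_sd * rng.standard_normal(len(w))
            - 0.5 * spec.subject_noise_sd**2
        )
        ws = w * g * e
        A = np.zeros_like(group.adjacency)
        A[iu, ju] = ws
        A[ju, iu] = ws
        subjects.append(
            NodeConnectome(A, list(group.node_labels), spec.absence_threshold)
        )
    return subjects


def cohort_edge_features(cohort: list[NodeConnectome]) -> np.ndarray:
    """Subjects x N(N-1)/2 matrix of aligned edge weights (absent pairs 0)."""
    rows = []
    for subj in cohort:
        el = build_edge_list(subj)
        rows.append(align_edge_values(el.weights, el))
    return np.vstack(rows)


def generate_phenotype(
    edge_features: np.ndarray,
    signal_edges: np.ndarray,
    r_squared: float,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Phenotype = linear combination of signal-edge features + scaled noise.

    Signal columns are standardized before combining (equal weights unless
    given) and the noise variance is set from the realized signal variance
    so the in-sample signal R^2 matches ``r_squared``.  ``r_squared=0``
    returns pure noise; ``r_squared=1`` is noiseless.
    """
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("r_squared must lie in [0, 1]")
    X = np.asarray(edge_features, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if r_squared == 0.0:
        return rng.standard_normal(n)
    signal_edges = np.asarray(signal_edges, dtype=int).reshape(-1)
    S = X[:, signal_edges]
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (S - S.mean(axis=0)) / sd
    w = np.ones(Z.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    signal = Z @ w
    var_s = signal.var()
    if var_s == 0:
        raise ValueError("planted signal has zero variance")
    if r_squared == 1.0:
        return signal
    noise_sd = np.sqrt(var_s * (1.0 - r_squared) / r_squared)
    return signal + noise_sd * rng.standard_normal(n)
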