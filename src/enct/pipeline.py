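"""End-to-end workflow: line graph -> controllability -> energy/nulls/CPM."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import DEFAULT_ABSENCE_THRESHOLD
from .controllability import edge_controllability, node_controllability
from .cpm import cross_validate
from .energy import (
    DEFAULT_HORIZON,
    DEFAULT_N_STEPS,
    decompose_energy_by_pairs,
    network_activation_energy,
)
from .io import (
    read_connectome,
    read_partition,
    read_subject_table,
    write_edge_list,
    write_manifest,
    write_matrix,
)
from .line_graph import align_edge_values, edge_network_from_connectome
from .nulls import DEFAULT_N_NULLS, DEFAULT_SWAPS_PER_EDGE, fdr_bh, null_pvalues
from .summaries import CanonicalPartition, whole_brain_sum

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one workflow run; defaults follow the standard protocol
    (absence threshold 0.001, T=1 with 1000 steps, 5000 nulls, CPM p<0.01)."""

    connectome_path: str
    output_dir: str
    partition_path: str | None = None
    features_path: str | None = None
    phenotype_path: str | None = None
    phenotype_column: str | None = None
    absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD
    horizon: float = DEFAULT_HORIZON
    n_steps: int = DEFAULT_N_STEPS
    rho: float = 1.0
    target_pair: str | None = None  # e.g. "FP-FP"; None skips the energy stage
    n_nulls: int = 0  # 0 skips the null stage (protocol default 5000)
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    fdr_q: float = 0.05
    cpm_p_threshold: float = 0.01
    cpm_k: int = 10
    cpm_repeats: int = 0  # 0 skips the CPM stage (protocol default 1000)
    seed: int = 0


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write artifacts plus a JSON manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "enct_version": __version__,
        "config": asdict(config),
        "stages": [],
    }

    conn = _stage("read_connectome")(read_connectome)(
        config.connectome_path, config.absence_threshold
    )
    manifest["n_nodes"] = conn.n_nodes

    @_stage("linegraph")
    def _linegraph():
        net = edge_network_from_connectome(conn)
        write_edge_list(net.edge_list, out / "edge_list.tsv")
        write_matrix(net.edge_adjacency, out / "edge_adjacency.csv")
        return net

    net = _linegraph()
    manifest["n_edges"] = net.L
    manifest["stages"].append("linegraph")

    @_stage("controllability")
    def _controllability():
        nprof = node_controllability(conn)
        eprof = edge_controllability(net)
        pd.DataFrame(
            {"node": conn.node_labels, "ac": nprof.ac, "mc": nprof.mc}
        ).to_csv(out / "node_controllability.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "node_i": net.edge_list.edges[:, 0],
                "node_j": net.edge_list.edges[:, 1],
                "eac": eprof.ac,
                "emc": eprof.mc,
            }
        ).to_csv(out / "edge_controllability.tsv", sep="\t", index=False)
        return nprof, eprof

    nprof, eprof = _controllability()
    manifest["stages"].append("controllability")
    manifest["stabilization_factor_edge"] = eprof.stabilization_factor
    manifest["eac_whole_brain"] = whole_brain_sum(eprof.ac)
    manifest["emc_whole_brain"] = whole_brain_sum(eprof.mc)

    partition = None
    if config.partition_path is not None:
        mapping = _stage("read_partition")(read_partition)(config.partition_path)
        partition = CanonicalPartition.from_mapping(mapping, conn.node_labels)

    if config.target_pair is not None:
        if partition is None:
            raise RuntimeError(
                "pipeline stage 'energy' failed: energy decomposition requested "
                "but no partition file was given"
            )

        @_stage("energy")
        def _energy():
            pair_labels = partition.pair_labels(net.edge_list)
            targets = np.flatnonzero(
                np.array(pair_labels) == config.target_pair
            )
            result, normalized = network_activation_energy(
                net,
                targets,
                horizon=config.horizon,
                n_steps=config.n_steps,
                rho=config.rho,
            )
            decompose_energy_by_pairs(result, pair_labels).to_csv(
                out / "energy_by_pair.tsv", sep="\t"
            )
            return result, normalized

        result, normalized = _energy()
        manifest["stages"].append("energy")
        manifest["energy_total"] = result.total_energy
        manifest["energy_normalized"] = normalized
        manifest["energy_terminal_error"] = result.terminal_error

    if config.n_nulls > 0:

        @_stage("nulls")
        def _nulls():
            def stat(c):
                prof = edge_controllability(edge_network_from_connectome(c))
                return np.array([whole_brain_sum(prof.ac), whole_brain_sum(prof.mc)])

            ens = null_pvalues(
                stat,
                conn,
                n_nulls=config.n_nulls,
                side="two-sided",
                seed=config.seed,
                swaps_per_edge=config.swaps_per_edge,
            )
            reject, q = fdr_bh(ens.p_values, config.fdr_q)
            pd.DataFrame(
                {
                    "statistic": ["eac_whole_brain", "emc_whole_brain"],
                    "empirical": ens.empirical_values,
                    "null_mean": ens.null_values.mean(axis=0),
                    "null_sd": ens.null_values.std(axis=0),
                    "p": ens.p_values,
                    "q": q,
                    "significant": reject,
                }
            ).to_csv(out / "null_tests.tsv", sep="\t", index=False)
            return ens

        _nulls()
        manifest["stages"].append("nulls")

    if config.cpm_repeats > 0:

        @_stage("cpm")
        def _cpm():
            feats = read_subject_table(config.features_path)
            pheno = read_subject_table(config.phenotype_path)
            col = config.phenotype_column or pheno.columns[0]
            common = feats.index.intersection(pheno.index)
            res = cross_validate(
                feats.loc[common].to_numpy(float),
                pheno.loc[common, col].to_numpy(float),
                k=config.cpm_k,
                n_repeats=config.cpm_repeats,
                p_threshold=config.cpm_p_threshold,
                seed=config.seed,
            )
            pd.DataFrame({"repeat": np.arange(res.n_repeats), "r": res.performance}
                         ).to_csv(out / "cpm_performance.tsv", sep="\t", index=False)
            return res

        res = _cpm()
        manifest["stages"].append("cpm")
        manifest["cpm_median_r"] = float(np.median(res.performance))

    write_manifest(manifest, out / "manifest.json")
    return manifest
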