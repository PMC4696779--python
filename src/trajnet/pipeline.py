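"""Config-driven end-to-end pipeline and synthetic fixture factory.

Stages: load → node map → align → fluctuation statistics → DCCM / PCA /
clustering → contact network → communities / centrality / paths.  The
run is deterministic for a fixed (config, seed): the JSON summary is
byte-identical across repeats and carries the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import corrpca, fluctuation, network as net
from .errors import PipelineError, SpecError
from .io import build_node_map, read_trajectory, write_trajectory
from .model import NodeMap, Trajectory
from .synthetic import (
    GaussianEnsembleSpec,
    TwoLobeMechanismSpec,
    generate_gaussian_ensemble,
    generate_two_lobe_trajectory,
    make_block_covariance,
    two_lobe_layout,
)

log = logging.getLogger("trajnet.pipeline")

FIXTURE_NAMES = ("two-lobe-default", "gaussian-antiblock")


@dataclass
class PipelineConfig:
    trajectory: str
    out_dir: str
    align_reference: int = 0
    contact_cutoff: float = 4.5
    persistence_min: float = 0.75
    contact_mode: str = "anchor"
    exclude_neighbors: int = 1
    cluster_k: int = 4
    cluster_components: tuple[int, ...] = (0, 1)
    cluster_restarts: int = 25
    elbow_k_max: int = 8
    path_source: str | None = None
    path_target: str | None = None
    path_delta: float | None = None
    suboptimal_max: int = 500
    seed: int = 0
    groups: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence_min <= 1.0:
            raise SpecError(
                f"persistence_min must lie in [0, 1], got {self.persistence_min}"
            )
        if self.contact_cutoff <= 0:
            raise SpecError("contact_cutoff must be positive")
        if self.contact_mode not in ("anchor", "heavy"):
            raise SpecError(f"unknown contact_mode {self.contact_mode!r}")
        if self.cluster_k < 1:
            raise SpecError("cluster_k must be >= 1")
        if self.path_delta is not None and self.path_delta < 0:
            raise SpecError("path_delta must be non-negative")
        self.cluster_components = tuple(int(c) for c in self.cluster_components)

    def to_json(self) -> str:
        d = asdict(self)
        d["cluster_components"] = list(self.cluster_components)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "cluster_components" in d:
            d["cluster_components"] = tuple(d["cluster_components"])
        return cls(**d)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _matrix_tsv(labels: list[str], m: np.ndarray, path: str) -> None:
    df = pd.DataFrame(m, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config: PipelineConfig,
                 traj: Trajectory | None = None) -> dict[str, Any]:
    """Execute every stage, write per-stage files and a JSON summary.

    A pre-loaded trajectory may be supplied to skip the file-reading
    stage.  Any stage failure raises :class:`PipelineError` naming the
    stage; completed stage outputs remain on disk.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.out_dir, "run.log"))
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict[str, Any] = {
        "config_hash": config.digest,
        "seed": config.seed,
    }
    try:
        out = config.out_dir

        def stage(name: str):
            log.info("stage %s", name)
            return name

        current = stage("load")
        if traj is None:
            traj = read_trajectory(config.trajectory)
        summary["n_frames"] = traj.n_frames

        current = stage("node_map")
        node_map = build_node_map(traj.topology)
        summary["n_nodes"] = len(node_map)

        current = stage("align")
        anchors = node_map.anchor_selection()
        aligned = fluctuation.align_trajectory(
            traj, anchors, reference_frame=config.align_reference
        )

        current = stage("rmsd")
        rmsd = fluctuation.rmsd_series(
            aligned, traj.frames[config.align_reference], anchors, superpose=True
        )
        _write_tsv(
            pd.DataFrame({"frame": np.arange(1, traj.n_frames + 1), "rmsd_A": rmsd}),
            os.path.join(out, "rmsd.tsv"),
        )
        summary["rmsd"] = {"mean": float(rmsd.mean()), "max": float(rmsd.max())}

        current = stage("rmsf")
        prof = fluctuation.rmsf_profile(aligned, anchors, aligned=True,
                                        labels=list(node_map.labels))
        rmsf_df = pd.DataFrame({"node": prof.labels, "rmsf_A": prof.rmsf})
        if prof.b_converted_rmsf is not None:
            rmsf_df["b_converted_rmsf_A"] = prof.b_converted_rmsf
        _write_tsv(rmsf_df, os.path.join(out, "rmsf.tsv"))
        summary["rmsf"] = {"mean": float(prof.rmsf.mean()),
                           "max": float(prof.rmsf.max())}

        current = stage("dccm")
        corr = corrpca.dccm(aligned, node_map)
        _matrix_tsv(corr.labels, corr.values, os.path.join(out, "dccm.tsv"))

        current = stage("distance_deviation")
        dmap = fluctuation.distance_deviation_map(traj, node_map)
        _matrix_tsv(dmap.labels, dmap.sigma, os.path.join(out, "devmap.tsv"))

        if config.groups:
            current = stage("group_blocks")
            summary["groups"] = _group_block_stats(config.groups, corr, dmap)

        current = stage("pca")
        pca = corrpca.pca_fit(aligned, node_map)
        fractions = pca.variance_fractions
        scree = pd.DataFrame({
            "rank": np.arange(1, len(pca.eigenvalues) + 1),
            "eigenvalue_A2": pca.eigenvalues,
            "fraction": fractions,
            "cumulative": np.cumsum(fractions),
        })
        _write_tsv(scree, os.path.join(out, "scree.tsv"))
        n_show = min(5, pca.projections.shape[1])
        proj_df = pd.DataFrame(
            pca.projections[:, :n_show],
            columns=[f"pc{i + 1}" for i in range(n_show)],
        )
        proj_df.insert(0, "frame", np.arange(1, traj.n_frames + 1))
        _write_tsv(proj_df, os.path.join(out, "projections.tsv"))
        summary["pca"] = {
            "fractions": [float(f) for f in fractions[:5]],
            "cumulative_3": float(np.cumsum(fractions)[min(2, len(fractions) - 1)]),
        }

        current = stage("cluster")
        pts = pca.projections[:, list(config.cluster_components)]
        km = corrpca.kmeans_cluster(pts, config.cluster_k,
                                    restarts=config.cluster_restarts,
                                    seed=config.seed)
        hc = corrpca.hierarchical_cluster(pts, config.cluster_k)
        elbow = corrpca.elbow_scan(
            pts, min(config.elbow_k_max, traj.n_frames), seed=config.seed
        )
        _write_tsv(
            pd.DataFrame({
                "frame": np.arange(1, traj.n_frames + 1),
                "kmeans": km.labels,
                "hierarchical": hc.labels,
            }),
            os.path.join(out, "clusters.tsv"),
        )
        summary["clustering"] = {
            "k": config.cluster_k,
            "kmeans_bss_tss": km.bss_tss,
            "hierarchical_bss_tss": hc.bss_tss,
            "method_agreement_ari": float(adjusted_rand_score(km.labels, hc.labels)),
            "elbow_suggested_k": elbow.suggested_k,
            "elbow_low_confidence": elbow.low_confidence,
        }

        current = stage("contacts")
        contacts = net.contact_persistence(
            traj, node_map, cutoff=config.contact_cutoff, mode=config.contact_mode
        )

        current = stage("network")
        network = net.build_network(
            contacts, corr,
            persistence_min=config.persistence_min,
            exclude_neighbors=config.exclude_neighbors,
            node_map=node_map,
        )
        edges = network.edge_list()
        _write_tsv(
            pd.DataFrame(edges, columns=["i", "j", "correlation", "distance"]),
            os.path.join(out, "edges.tsv"),
        )
        _write_graphml(network, os.path.join(out, "network.graphml"))
        summary["network"] = {
            "n_edges": network.graph.number_of_edges(),
            "n_nodes": network.graph.number_of_nodes(),
        }

        current = stage("communities")
        partition = net.girvan_newman(network)
        _write_tsv(
            pd.DataFrame({
                "node": list(network.labels),
                "community": [partition.community_of[n] for n in network.labels],
            }),
            os.path.join(out, "communities.tsv"),
        )
        sizes = sorted((len(c) for c in partition.communities), reverse=True)
        summary["communities"] = {
            "n": partition.n_communities,
            "modularity": partition.modularity,
            "sizes": sizes,
        }

        current = stage("centrality")
        centrality = net.betweenness(network)
        criticals = net.critical_nodes(network, partition, centrality)
        summary["critical_nodes"] = criticals

        if config.path_source and config.path_target:
            current = stage("distance_series")
            ds = fluctuation.distance_series(
                traj, node_map, config.path_source, config.path_target
            )
            _write_tsv(
                pd.DataFrame({"frame": np.arange(1, traj.n_frames + 1),
                              "distance_A": ds.values}),
                os.path.join(out, "endpoint_distance.tsv"),
            )
            summary["endpoint_distance"] = {
                "pair": list(ds.pair),
                "min": float(ds.values.min()),
                "max": float(ds.values.max()),
            }

            current = stage("paths")
            pathset = net.suboptimal_paths(
                network, config.path_source, config.path_target,
                delta=config.path_delta, max_paths=config.suboptimal_max,
            )
            rows = [
                {"rank": r + 1, "length": l, "path": "|".join(p)}
                for r, (p, l) in enumerate(pathset.suboptimal)
            ]
            _write_tsv(pd.DataFrame(rows), os.path.join(out, "paths.tsv"))
            summary["paths"] = {
                "source": pathset.source,
                "target": pathset.target,
                "optimal_length": pathset.optimal[1],
                "optimal_path": pathset.optimal[0],
                "n_paths": len(pathset.suboptimal),
                "delta": pathset.tolerance,
                "truncated": pathset.truncated,
            }
            if config.groups and "connectors" in config.groups:
                conn = {network.labels[i] for i in config.groups["connectors"]}
                crossing = sum(
                    any(u in conn and v in conn for u, v in zip(p, p[1:]))
                    for p, _ in pathset.suboptimal
                )
                summary["paths"]["bridge_crossing_fraction"] = (
                    crossing / len(pathset.suboptimal)
                )
    except PipelineError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", current, exc)
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    return summary


def _group_block_stats(groups: dict[str, list[int]],
                       corr: corrpca.CorrelationMatrix,
                       dmap: fluctuation.DistanceDeviationMap) -> dict[str, Any]:
    out: dict[str, Any] = {}
    names = sorted(groups)
    for gi in range(len(names)):
        for gj in range(gi + 1, len(names)):
            a = np.asarray(groups[names[gi]], dtype=int)
            b = np.asarray(groups[names[gj]], dtype=int)
            if set(a.tolist()) & set(b.tolist()):
                continue
            key = f"{names[gi]}|{names[gj]}"
            out[key] = {
                "dccm_block_mean": float(corr.values[np.ix_(a, b)].mean()),
                "deviation_ratio": fluctuation.block_deviation_ratio(
                    dmap, (a, b)
                ),
            }
    return out


def _write_graphml(network: net.DynamicalNetwork, path: str) -> None:
    import networkx as nx

    nx.write_graphml(network.graph, path)


def simulate_fixture(
    name: str,
    seed: int,
    out_dir: str,
    overrides: dict[str, Any] | None = None,
) -> tuple[str, str]:
    """Write a named synthetic fixture: trajectory PDB plus a truth JSON.

    The truth file records the planted structure (groups, spec, labels)
    consumed by test harnesses and by downstream pipeline configs.
    Returns (trajectory path, truth path).
    """
    if name not in FIXTURE_NAMES:
        raise SpecError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    os.makedirs(out_dir, exist_ok=True)
    traj_path = os.path.join(out_dir, f"{name}.pdb")
    truth_path = os.path.join(out_dir, f"{name}.truth.json")
    overrides = dict(overrides or {})
    if name == "two-lobe-default":
        spec = TwoLobeMechanismSpec(seed=seed, **overrides)
        traj, layout = generate_two_lobe_trajectory(spec)
        labels = [f"A:GLY{i + 1}" for i in range(layout.coords.shape[0])]
        truth = {
            "fixture": name,
            "spec": json.loads(spec.to_json()),
            "labels": labels,
            "groups": {
                "lobe_a": layout.lobe_a,
                "bridge": layout.bridge,
                "lobe_b": layout.lobe_b,
                "connectors": layout.connectors,
            },
            "bridge_labels": [labels[i] for i in layout.bridge],
            "suggested_endpoints": [
                labels[layout.lobe_a[
                    int(np.argmin(layout.coords[layout.lobe_a, 0]))
                ]],
                labels[layout.lobe_b[
                    int(np.argmax(layout.coords[layout.lobe_b, 0]))
                ]],
            ],
        }
    else:  # gaussian-antiblock
        params = {
            "n_nodes": 40, "block_sizes": [20, 20],
            "intra": 0.7, "inter": -0.6, "sigma2": 0.25,
            "n_frames": 2000,
        }
        params.update(overrides)
        cov = make_block_covariance(
            params["block_sizes"], params["intra"], params["inter"],
            params["sigma2"],
        )
        n = sum(params["block_sizes"])
        mean = np.column_stack(
            [np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]
        )
        spec = GaussianEnsembleSpec(
            mean_structure=mean, displacement_covariance=cov,
            n_frames=params["n_frames"], seed=seed,
        )
        traj = generate_gaussian_ensemble(spec)
        truth = {
            "fixture": name,
            "covariance_params": params,
            "labels": [f"A:GLY{i + 1}" for i in range(n)],
            "groups": {
                "block_a": list(range(params["block_sizes"][0])),
                "block_b": list(range(params["block_sizes"][0], n)),
            },
            "planted_inter_correlation": params["inter"],
            "planted_intra_correlation": params["intra"],
        }
    write_trajectory(traj, traj_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
    return traj_path, truth_path
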