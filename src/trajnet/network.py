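"""Correlation-weighted dynamical networks: contacts, communities,
centrality, critical nodes and optimal/suboptimal paths.

Edges join node pairs in persistent contact; each edge carries the motion
correlation C_ij of its endpoints and the derived communication distance
w_ij = −ln|C_ij| (strongly correlated pairs are "close").  All outputs are
deterministic: ties are broken by lowest node index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import NoPathError, SelectionError
from .model import NodeMap, Trajectory
from .corrpca import CorrelationMatrix


@dataclass
class ContactStatistics:
    """Fraction of frames each node pair spends in contact."""

    labels: list[str]
    persistence: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.persistence, dtype=float)
        if p.min() < 0 or p.max() > 1:
            raise ValueError("persistence fractions must lie in [0, 1]")
        self.persistence = p


@dataclass
class DynamicalNetwork:
    """Weighted undirected graph over node-map labels.

    Edge attributes: ``correlation`` (C_ij) and ``distance``
    (w_ij = −ln|C_ij| ≥ 0).
    """

    labels: list[str]
    graph: nx.Graph

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def edge_list(self) -> list[tuple[str, str, float, float]]:
        ix = self.index
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v), key=ix.__getitem__)
            rows.append((a, b, data["correlation"], data["distance"]))
        rows.sort(key=lambda r: (ix[r[0]], ix[r[1]]))
        return rows


@dataclass
class CommunityPartition:
    community_of: dict[str, int]
    modularity: float

    @property
    def communities(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.community_of.items():
            out.setdefault(c, []).append(node)
        return [out[c] for c in sorted(out)]

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))


@dataclass
class CentralityProfile:
    node_betweenness: dict[str, float]
    edge_betweenness: dict[tuple[str, str], float]


@dataclass
class PathSet:
    source: str
    target: str
    optimal: tuple[list[str], float]
    suboptimal: list[tuple[list[str], float]]  # includes the optimal, ascending
    tolerance: float
    truncated: bool = False


def contact_persistence(
    traj: Trajectory,
    node_map: NodeMap,
    cutoff: float = 4.5,
    mode: str = "anchor",
) -> ContactStatistics:
    """Fraction of frames in which node pairs lie within ``cutoff`` Å.

    ``anchor`` measures anchor-atom distances; ``heavy`` measures the
    minimum distance between the nodes' heavy-atom sets (falls back to the
    anchor when a node owns a single atom).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("anchor", "heavy"):
        raise ValueError(f"unknown contact mode {mode!r}")
    n = len(node_map)
    counts = np.zeros((n, n))
    if mode == "anchor":
        idx = node_map.anchor_indices
        for f in range(traj.n_frames):
            d = cdist(traj.frames[f, idx], traj.frames[f, idx])
            counts += d < cutoff
    else:
        atom_node = np.full(traj.n_atoms, -1, dtype=int)
        for i, atoms in enumerate(node_map.residue_atoms):
            for a in atoms:
                atom_node[a] = i
        owned = np.where(atom_node >= 0)[0]
        for f in range(traj.n_frames):
            xyz = traj.frames[f][owned]
            tree = cKDTree(xyz)
            hit = np.zeros((n, n), dtype=bool)
            for a, b in tree.query_pairs(cutoff):
                i, j = atom_node[owned[a]], atom_node[owned[b]]
                if i != j:
                    hit[i, j] = hit[j, i] = True
            counts += hit
    p = counts / traj.n_frames
    np.fill_diagonal(p, 0.0)
    return ContactStatistics(labels=list(node_map.labels), persistence=p)


def build_network(
    contacts: ContactStatistics,
    corr: CorrelationMatrix,
    persistence_min: float = 0.75,
    exclude_neighbors: int = 1,
    node_map: NodeMap | None = None,
) -> DynamicalNetwork:
    """Edges where persistence ≥ threshold, weighted by w = −ln|C|.

    Sequence neighbours within ``exclude_neighbors`` positions are not
    linked (bonded pairs are trivially in contact and would short-circuit
    communication paths).  Edges with C = 0 are dropped with a warning.
    """
    if contacts.labels != corr.labels:
        raise SelectionError("contact and correlation matrices use different nodes")
    n = len(contacts.labels)
    g = nx.Graph()
    g.add_nodes_from(contacts.labels)
    dropped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if contacts.persistence[i, j] < persistence_min:
                continue
            if _sequence_neighbors(i, j, node_map, exclude_neighbors):
                continue
            c = float(corr.values[i, j])
            if abs(c) < 1e-12:
                dropped += 1
                continue
            w = -np.log(min(abs(c), 1.0))
            g.add_edge(contacts.labels[i], contacts.labels[j],
                       correlation=c, strength=abs(c), distance=float(w))
    if dropped:
        warnings.warn(
            f"{dropped} persistent contact(s) had zero correlation and were "
            "dropped from the network",
            stacklevel=2,
        )
    return DynamicalNetwork(labels=list(contacts.labels), graph=g)


def _sequence_neighbors(
    i: int, j: int, node_map: NodeMap | None, exclude: int
) -> bool:
    if exclude <= 0:
        return False
    if node_map is None:
        return abs(i - j) <= exclude
    if node_map.is_ligand[i] or node_map.is_ligand[j]:
        return False
    if node_map.chain_ids and node_map.chain_ids[i] != node_map.chain_ids[j]:
        return False
    return abs(node_map.residue_seqs[i] - node_map.residue_seqs[j]) <= exclude


def _edge_key(network: DynamicalNetwork, u: str, v: str) -> tuple[str, str]:
    ix = network.index
    return (u, v) if ix[u] <= ix[v] else (v, u)


def girvan_newman(
    network: DynamicalNetwork, weighted_modularity: bool = False
) -> CommunityPartition:
    """Divisive community detection by edge-betweenness removal.

    Edges of highest betweenness (computed with the w_ij distances) are
    removed iteratively; the returned partition is the one of maximum
    modularity over the whole removal sequence.  Modularity is scored on
    the original graph with the unweighted edge-count form by default.
    """
    if network.graph.number_of_edges() == 0 and network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    ix = network.index
    original = network.graph
    work = original.copy()

    def score(components: list[set[str]]) -> float:
        if original.number_of_edges() == 0:
            return 0.0
        return nx.algorithms.community.modularity(
            original, components, weight="strength" if weighted_modularity else None
        )

    best_components = [set(c) for c in nx.connected_components(work)]
    best_q = score(best_components)
    n_comp = len(best_components)
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, normalized=False, weight="distance")
        target = max(
            eb.items(),
            key=lambda kv: (kv[1], -ix[min(kv[0], key=ix.__getitem__)],
                            -ix[max(kv[0], key=ix.__getitem__)]),
        )[0]
        work.remove_edge(*target)
        components = [set(c) for c in nx.connected_components(work)]
        if len(components) > n_comp:
            n_comp = len(components)
            q = score(components)
            if q > best_q + 1e-12:
                best_q = q
                best_components = components
    community_of: dict[str, int] = {}
    ordered = sorted(best_components, key=lambda c: min(ix[n] for n in c))
    for c_index, members in enumerate(ordered):
        for node in members:
            community_of[node] = c_index
    return CommunityPartition(community_of=community_of, modularity=float(best_q))


def betweenness(network: DynamicalNetwork) -> CentralityProfile:
    """Shortest-path betweenness under the w_ij edge distances.

    Unnormalized; each unordered pair contributes 1, shared fractionally
    among equal-length shortest paths.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    nb = nx.betweenness_centrality(network.graph, normalized=False, weight="distance")
    eb = nx.edge_betweenness_centrality(
        network.graph, normalized=False, weight="distance"
    )
    edge_b = {_edge_key(network, u, v): b for (u, v), b in eb.items()}
    return CentralityProfile(node_betweenness=dict(nb), edge_betweenness=edge_b)


def critical_nodes(
    network: DynamicalNetwork,
    partition: CommunityPartition,
    centrality: CentralityProfile,
) -> list[str]:
    """Endpoints of the strongest inter-community edges.

    For every community pair joined by at least one edge, the connecting
    edge of maximum edge betweenness is selected and both its endpoints
    are reported."""
    ix = network.index
    best: dict[tuple[int, int], tuple[float, tuple[str, str]]] = {}
    for u, v in network.graph.edges():
        cu, cv = partition.community_of[u], partition.community_of[v]
        if cu == cv:
            continue
        pair = (min(cu, cv), max(cu, cv))
        key = _edge_key(network, u, v)
        b = centrality.edge_betweenness.get(key, 0.0)
        cand = (b, key)
        prev = best.get(pair)
        # tie-break toward the lexicographically smallest edge by node index
        if prev is None or cand[0] > prev[0] + 1e-12 or (
            abs(cand[0] - prev[0]) <= 1e-12
            and (ix[key[0]], ix[key[1]]) < (ix[prev[1][0]], ix[prev[1][1]])
        ):
            best[pair] = cand
    nodes: set[str] = set()
    for _, (u, v) in best.values():
        nodes.update((u, v))
    return sorted(nodes, key=ix.__getitem__)


def optimal_path(
    network: DynamicalNetwork, source: str, target: str
) -> tuple[list[str], float]:
    """Minimum-total-w path; among ties, lowest node-index sequence."""
    g = network.graph
    if source not in g or target not in g:
        raise SelectionError(f"unknown endpoint {source!r} or {target!r}")
    if source == target:
        return [source], 0.0
    try:
        length = nx.dijkstra_path_length(g, source, target, weight="distance")
        ix = network.index
        paths = nx.all_shortest_paths(g, source, target, weight="distance")
        best = min(paths, key=lambda p: [ix[n] for n in p])
    except nx.NetworkXNoPath:
        raise NoPathError(f"no path between {source!r} and {target!r}") from None
    return best, float(length)


def suboptimal_paths(
    network: DynamicalNetwork,
    source: str,
    target: str,
    delta: float | None = None,
    max_paths: int = 1000,
) -> PathSet:
    """All simple paths within ``delta`` of the optimal length.

    Default delta = 0.2 · L_opt.  Paths are returned ascending by length
    (ties by node-index sequence); the optimal path is first.  The list is
    truncated at ``max_paths`` with the ``truncated`` flag set.
    """
    opt_path, l_opt = optimal_path(network, source, target)
    if delta is None:
        delta = 0.2 * l_opt
    if delta < 0:
        raise ValueError("delta must be non-negative")
    g = network.graph
    budget = l_opt + delta + 1e-9
    dist_to_target = nx.single_source_dijkstra_path_length(
        g, target, weight="distance"
    )
    ix = network.index
    found: list[tuple[float, list[str]]] = []
    hard_cap = max(100000, 10 * max_paths)

    def dfs(node: str, length: float, path: list[str], on_path: set[str]) -> None:
        if len(found) >= hard_cap:
            return
        if node == target:
            found.append((length, list(path)))
            return
        for nbr in sorted(g.neighbors(node), key=ix.__getitem__):
            if nbr in on_path:
                continue
            step = length + g[node][nbr]["distance"]
            if step + dist_to_target.get(nbr, np.inf) > budget:
                continue
            path.append(nbr)
            on_path.add(nbr)
            dfs(nbr, step, path, on_path)
            path.pop()
            on_path.remove(nbr)

    if source == target:
        found = [(0.0, [source])]
    else:
        dfs(source, 0.0, [source], {source})
    found.sort(key=lambda lp: (lp[0], [ix[n] for n in lp[1]]))
    truncated = len(found) > max_paths or len(found) >= hard_cap
    found = found[:max_paths]
    return PathSet(
        source=source,
        target=target,
        optimal=(opt_path, l_opt),
        suboptimal=[(p, l) for l, p in found],
        tolerance=float(delta),
        truncated=truncated,
    )


def edge_path_usage(pathset: PathSet) -> dict[tuple[str, str], int]:
    """Number of (sub)optimal paths crossing each edge."""
    if not pathset.suboptimal:
        raise ValueError("empty path set")
    usage: dict[tuple[str, str], int] = {}
    for path, _ in pathset.suboptimal:
        for u, v in zip(path, path[1:]):
            key = (u, v) if u <= v else (v, u)
            usage[key] = usage.get(key, 0) + 1
    return usage
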