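"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, derivative-free
optimisation) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def enumerate_simple_paths(adj: dict, s, t, path=None):
    """Yield every simple path s→t as a list of nodes."""
    if path is None:
        path = [s]
    if s == t:
        yield list(path)
        return
    for v in adj[s]:
        if v in path:
            continue
        path.append(v)
        yield from enumerate_simple_paths(adj, v, t, path)
        path.pop()


def graph_adj(graph) -> dict:
    return {n: sorted(graph.neighbors(n)) for n in graph.nodes}


def path_length(graph, path, weight="distance") -> float:
    return sum(graph[u][v][weight] for u, v in zip(path, path[1:]))


def brute_shortest(graph, s, t, weight="distance"):
    """(min length, list of all equally-shortest simple paths)."""
    adj = graph_adj(graph)
    best = math.inf
    shortest = []
    for p in enumerate_simple_paths(adj, s, t):
        l = path_length(graph, p, weight)
        if l < best - 1e-12:
            best, shortest = l, [p]
        elif abs(l - best) <= 1e-12:
            shortest.append(p)
    return best, shortest


def brute_paths_within(graph, s, t, budget, weight="distance"):
    """All simple paths with length ≤ budget, as (length, path) sorted."""
    adj = graph_adj(graph)
    out = []
    for p in enumerate_simple_paths(adj, s, t):
        l = path_length(graph, p, weight)
        if l <= budget + 1e-9:
            out.append((l, p))
    out.sort(key=lambda lp: lp[0])
    return out


def brute_betweenness(graph, weight="distance"):
    """Unnormalized node and edge betweenness by all-pairs enumeration.

    Each unordered pair contributes 1, split evenly among its shortest
    paths; path endpoints receive no node credit.
    """
    node_b = {n: 0.0 for n in graph.nodes}
    edge_b = {tuple(sorted(e)): 0.0 for e in graph.edges}
    nodes = sorted(graph.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            best, shortest = brute_shortest(graph, s, t, weight)
            if not shortest:
                continue
            share = 1.0 / len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    node_b[v] += share
                for u, v in zip(p, p[1:]):
                    edge_b[tuple(sorted((u, v)))] += share
    return node_b, edge_b


def set_partitions(items):
    """Yield all set partitions of a sequence (lists of lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_unweighted(graph, communities) -> float:
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        cset = set(comm)
        internal = sum(1 for u, v in graph.edges if u in cset and v in cset)
        degree = sum(graph.degree(n) for n in cset)
        q += internal / m - (degree / (2.0 * m)) ** 2
    return q


def exhaustive_max_modularity(graph):
    """Best (Q, partition) over every set partition of the nodes."""
    best_q = -math.inf
    best = None
    for part in set_partitions(sorted(graph.nodes)):
        q = modularity_unweighted(graph, part)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best_q, frozenset(frozenset(c) for c in best)


def numeric_superpose_rmsd(mobile, reference) -> float:
    """Minimum RMSD over rigid transforms by derivative-free optimisation."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def cost(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(mob_c)
        return np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1)))

    best = math.inf
    for guess in itertools.product((-1.5, 0.0, 1.5), repeat=3):
        res = minimize(cost, np.array(guess), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


def brute_block_ratio(sigma, a, b) -> float:
    """Two-loop re-implementation of the block deviation ratio."""
    n = sigma.shape[0]
    cross, n_cross = 0.0, 0
    off, n_off = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            off += sigma[i, j]
            n_off += 1
            if i in a and j in b:
                cross += sigma[i, j]
                n_cross += 1
    return (cross / n_cross) / (off / n_off)
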