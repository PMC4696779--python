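import networkx as nx
import numpy as np
import pytest

from trajnet.model import AtomRecord, Structure, Trajectory
from trajnet.network import DynamicalNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ca_structure(coords, resnames=None, b_factors=None):
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    resnames = resnames or ["ALA"] * n
    b = b_factors if b_factors is not None else np.zeros(n)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", residue_name=resnames[i],
                   chain_id="A", residue_seq=i + 1, coords=coords[i],
                   b_factor=float(b[i]), element="C")
        for i in range(n)
    ]
    return Structure(atoms)


def make_trajectory(frames):
    frames = np.asarray(frames, float)
    return Trajectory(frames, make_ca_structure(frames[0]))


def random_network(n_nodes, edge_prob, seed):
    """Connected random graph with U(0.2, 2.0) edge distances."""
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        g = nx.Graph()
        labels = [f"n{i}" for i in range(n_nodes)]
        g.add_nodes_from(labels)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    d = float(rng.uniform(0.2, 2.0))
                    g.add_edge(labels[i], labels[j], distance=d,
                               correlation=float(np.exp(-d)),
                               strength=float(np.exp(-d)))
        if g.number_of_edges() and nx.is_connected(g):
            return DynamicalNetwork(labels=labels, graph=g)
        rng = np.random.default_rng(seed * 1000 + attempt + 1)
    raise RuntimeError("failed to build a connected random graph")


@pytest.fixture
def two_clique_bridge():
    """Two 3-cliques joined by one bridge edge; max-modularity Q = 5/14."""
    g = nx.Graph()
    labels = [f"n{i}" for i in range(6)]
    for block in (labels[:3], labels[3:]):
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(block[i], block[j], distance=0.3,
                           correlation=float(np.exp(-0.3)),
                           strength=float(np.exp(-0.3)))
    g.add_edge(labels[2], labels[3], distance=1.5,
               correlation=float(np.exp(-1.5)), strength=float(np.exp(-1.5)))
    return DynamicalNetwork(labels=labels, graph=g)
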