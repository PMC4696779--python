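import networkx as nx
import numpy as np
import pytest

from trajnet.corrpca import CorrelationMatrix, dccm
from trajnet.errors import NoPathError, SelectionError
from trajnet.fluctuation import align_trajectory
from trajnet.model import identity_node_map
from trajnet.network import (
    ContactStatistics,
    DynamicalNetwork,
    betweenness,
    build_network,
    contact_persistence,
    critical_nodes,
    edge_path_usage,
    girvan_newman,
    optimal_path,
    suboptimal_paths,
)
from trajnet.synthetic import (
    TwoLobeMechanismSpec,
    generate_planted_graph,
    generate_two_lobe_trajectory,
)

from conftest import make_trajectory, random_network
from oracles import (
    brute_betweenness,
    brute_paths_within,
    brute_shortest,
    exhaustive_max_modularity,
)


def simple_network(edges):
    """Network from (u, v, distance) triples; labels sorted."""
    labels = sorted({n for e in edges for n in e[:2]})
    g = nx.Graph()
    g.add_nodes_from(labels)
    for u, v, d in edges:
        g.add_edge(u, v, distance=float(d), correlation=float(np.exp(-d)),
                   strength=float(np.exp(-d)))
    return DynamicalNetwork(labels=labels, graph=g)


class TestContactPersistence:
    def _pair_traj(self, distance, n_frames=10):
        frames = np.zeros((n_frames, 2, 3))
        frames[:, 1, 0] = distance
        return make_trajectory(frames)

    def test_pair_within_cutoff(self):
        traj = self._pair_traj(4.0)
        cs = contact_persistence(traj, identity_node_map(2), cutoff=4.5)
        assert cs.persistence[0, 1] == 1.0

    def test_pair_beyond_cutoff(self):
        traj = self._pair_traj(5.0)
        cs = contact_persistence(traj, identity_node_map(2), cutoff=4.5)
        assert cs.persistence[0, 1] == 0.0

    def test_seventy_percent_excluded_at_threshold(self):
        # threshold semantics: < cutoff in exactly 70% of frames -> p=0.70,
        # excluded by the >= 75% rule; 75% -> included
        frames = np.zeros((20, 2, 3))
        frames[:14, 1, 0] = 4.0   # 14/20 = 70% in contact
        frames[14:, 1, 0] = 6.0
        traj = make_trajectory(frames)
        nm = identity_node_map(2)
        cs = contact_persistence(traj, nm, cutoff=4.5)
        assert cs.persistence[0, 1] == pytest.approx(0.70)
        corr = CorrelationMatrix(labels=list(nm.labels),
                                 values=np.array([[1.0, 0.5], [0.5, 1.0]]))
        net70 = build_network(cs, corr, persistence_min=0.75, exclude_neighbors=0)
        assert net70.graph.number_of_edges() == 0
        frames[:15, 1, 0] = 4.0   # now 75%
        cs2 = contact_persistence(make_trajectory(frames), nm, cutoff=4.5)
        assert cs2.persistence[0, 1] == pytest.approx(0.75)
        net75 = build_network(cs2, corr, persistence_min=0.75, exclude_neighbors=0)
        assert net75.graph.number_of_edges() == 1

    def test_heavy_mode_uses_minimum_atom_distance(self):
        # two "residues" of 2 atoms each; anchors far apart but side atoms close
        frames = np.zeros((2, 4, 3))
        frames[:, 0] = [0, 0, 0]      # res1 anchor
        frames[:, 1] = [0, 3, 0]      # res1 side atom
        frames[:, 2] = [10, 0, 0]     # res2 anchor
        frames[:, 3] = [0, 6, 0]      # res2 side atom: 3 Å from res1 side
        traj = make_trajectory(frames)
        nm = identity_node_map(4)
        nm = type(nm)(labels=["r1", "r2"], anchor_indices=np.array([0, 2]),
                      chain_ids=["A", "A"], residue_seqs=[1, 2],
                      is_ligand=np.array([False, False]),
                      residue_atoms=[(0, 1), (2, 3)])
        anchor = contact_persistence(traj, nm, cutoff=4.5, mode="anchor")
        heavy = contact_persistence(traj, nm, cutoff=4.5, mode="heavy")
        assert anchor.persistence[0, 1] == 0.0
        assert heavy.persistence[0, 1] == 1.0

    def test_bad_cutoff(self):
        traj = self._pair_traj(4.0)
        with pytest.raises(ValueError):
            contact_persistence(traj, identity_node_map(2), cutoff=0.0)


class TestBuildNetwork:
    def _contacts_corr(self, p, c):
        labels = [f"n{i}" for i in range(p.shape[0])]
        return (ContactStatistics(labels=labels, persistence=p),
                CorrelationMatrix(labels=labels, values=c))

    def test_edge_weight_closed_forms(self):
        p = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        c[0, 2] = c[2, 0] = np.exp(-1.0)
        c[1, 2] = c[2, 1] = 0.5
        contacts, corr = self._contacts_corr(p, c)
        net = build_network(contacts, corr, persistence_min=0.75,
                            exclude_neighbors=0)
        assert net.graph["n0"]["n1"]["distance"] == pytest.approx(0.0)
        assert net.graph["n0"]["n2"]["distance"] == pytest.approx(1.0)
        assert net.graph["n1"]["n2"]["distance"] == pytest.approx(-np.log(0.5))

    def test_edge_count_matches_threshold(self):
        n = 6
        p = np.zeros((n, n))
        pairs = [(0, 3), (1, 4), (2, 5)]
        for i, j in pairs:
            p[i, j] = p[j, i] = 0.9
        p[0, 1] = p[1, 0] = 0.5  # below threshold
        c = np.full((n, n), 0.4)
        np.fill_diagonal(c, 1.0)
        contacts, corr = self._contacts_corr(p, c)
        net = build_network(contacts, corr, persistence_min=0.75,
                            exclude_neighbors=1)
        assert net.graph.number_of_edges() == 3

    def test_neighbor_exclusion_monotone(self):
        rng = np.random.default_rng(0)
        n = 8
        p = rng.uniform(0, 1, (n, n))
        p = (p + p.T) / 2
        np.fill_diagonal(p, 0)
        c = np.full((n, n), 0.5)
        np.fill_diagonal(c, 1.0)
        contacts, corr = self._contacts_corr(p, c)
        prev = None
        for pm in (0.2, 0.5, 0.8):
            net = build_network(contacts, corr, persistence_min=pm,
                                exclude_neighbors=1)
            edges = set(net.graph.edges())
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_zero_correlation_edge_dropped_with_warning(self):
        p = np.array([[0, 1.0], [1.0, 0]])
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        contacts, corr = self._contacts_corr(p, c)
        with pytest.warns(UserWarning, match="zero correlation"):
            net = build_network(contacts, corr, exclude_neighbors=0)
        assert net.graph.number_of_edges() == 0

    def test_mismatched_labels_rejected(self):
        contacts, _ = self._contacts_corr(np.zeros((2, 2)), np.eye(2))
        corr = CorrelationMatrix(labels=["x", "y"], values=np.eye(2))
        with pytest.raises(SelectionError):
            build_network(contacts, corr)


class TestGirvanNewman:
    def test_two_clique_bridge(self, two_clique_bridge):
        part = girvan_newman(two_clique_bridge)
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(5.0 / 14.0, abs=1e-12)
        got = frozenset(frozenset(c) for c in part.communities)
        assert got == frozenset(
            (frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"}))
        )

    def test_single_clique_one_community(self):
        edges = [(f"n{i}", f"n{j}", 0.5) for i in range(4) for j in range(i + 1, 4)]
        part = girvan_newman(simple_network(edges))
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_modularity_on_planted_graphs(self, seed):
        net, _ = generate_planted_graph(2, 4, [(1, 5)], seed=seed)
        part = girvan_newman(net)
        best_q, best_part = exhaustive_max_modularity(net.graph)
        assert part.modularity == pytest.approx(best_q, abs=1e-12)
        assert frozenset(frozenset(c) for c in part.communities) == best_part

    def test_nine_planted_communities_recovered(self):
        bridges = [(i * 4, ((i + 1) % 9) * 4 + 1) for i in range(9)]
        net, planted = generate_planted_graph(9, 4, bridges, seed=3)
        part = girvan_newman(net)
        assert part.n_communities == 9
        from sklearn.metrics import adjusted_rand_score

        found = [part.community_of[l] for l in net.labels]
        assert adjusted_rand_score(planted, found) == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            girvan_newman(DynamicalNetwork(labels=[], graph=nx.Graph()))


class TestBetweenness:
    def test_path_graph_center(self):
        net = simple_network([("a", "b", 1.0), ("b", "c", 1.0)])
        prof = betweenness(net)
        assert prof.node_betweenness["b"] == pytest.approx(1.0)
        assert prof.node_betweenness["a"] == 0.0
        assert prof.node_betweenness["c"] == 0.0

    def test_star_center_on_all_pairs(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        net = simple_network(edges)
        prof = betweenness(net)
        assert prof.node_betweenness["hub"] == pytest.approx(10.0)  # C(5,2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        net = random_network(n_nodes=9, edge_prob=0.35, seed=seed)
        prof = betweenness(net)
        node_b, edge_b = brute_betweenness(net.graph)
        for n in net.labels:
            assert prof.node_betweenness[n] == pytest.approx(node_b[n], abs=1e-9)
        for e, b in edge_b.items():
            key = tuple(sorted(e, key=net.index.__getitem__))
            assert prof.edge_betweenness[key] == pytest.approx(b, abs=1e-9)


class TestCriticalNodes:
    def test_two_clique_bridge_endpoints(self, two_clique_bridge):
        part = girvan_newman(two_clique_bridge)
        prof = betweenness(two_clique_bridge)
        crit = critical_nodes(two_clique_bridge, part, prof)
        assert crit == ["n2", "n3"]

    def test_single_community_empty(self):
        edges = [(f"n{i}", f"n{j}", 0.5) for i in range(4) for j in range(i + 1, 4)]
        net = simple_network(edges)
        part = girvan_newman(net)
        prof = betweenness(net)
        assert critical_nodes(net, part, prof) == []


class TestOptimalPath:
    def test_triangle(self):
        net = simple_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        path, length = optimal_path(net, "A", "C")
        assert path == ["A", "B", "C"]
        assert length == pytest.approx(2.0)

    def test_source_equals_target(self):
        net = simple_network([("A", "B", 1.0)])
        assert optimal_path(net, "A", "A") == (["A"], 0.0)

    def test_disconnected_raises(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        net = DynamicalNetwork(labels=["A", "B"], graph=g)
        with pytest.raises(NoPathError):
            optimal_path(net, "A", "B")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        net = random_network(n_nodes=8, edge_prob=0.4, seed=100 + seed)
        labels = net.labels
        best, shortest = brute_shortest(net.graph, labels[0], labels[-1])
        path, length = optimal_path(net, labels[0], labels[-1])
        assert length == pytest.approx(best, abs=1e-9)
        assert path in shortest


class TestSuboptimalPaths:
    def test_triangle_with_tolerance(self):
        net = simple_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        ps = suboptimal_paths(net, "A", "C", delta=1.5)
        assert [(p, pytest.approx(l)) for p, l in ps.suboptimal] == [
            (["A", "B", "C"], pytest.approx(2.0)),
            (["A", "C"], pytest.approx(3.0)),
        ]
        assert not ps.truncated

    def test_zero_delta_optimal_only(self):
        net = simple_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        ps = suboptimal_paths(net, "A", "C", delta=0.0)
        assert [p for p, _ in ps.suboptimal] == [["A", "B", "C"]]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("delta_frac", [0.0, 0.5])
    def test_matches_bounded_enumeration(self, seed, delta_frac):
        net = random_network(n_nodes=8, edge_prob=0.4, seed=200 + seed)
        s, t = net.labels[0], net.labels[-1]
        l_opt, _ = brute_shortest(net.graph, s, t)
        delta = delta_frac * l_opt
        expected = brute_paths_within(net.graph, s, t, l_opt + delta)
        ps = suboptimal_paths(net, s, t, delta=delta, max_paths=10000)
        assert len(ps.suboptimal) == len(expected)
        got_lengths = [l for _, l in ps.suboptimal]
        np.testing.assert_allclose(got_lengths, [l for l, _ in expected],
                                   atol=1e-9)
        assert {tuple(p) for p, _ in ps.suboptimal} == {
            tuple(p) for _, p in expected
        }

    def test_delta_monotonicity(self):
        net = random_network(n_nodes=9, edge_prob=0.4, seed=7)
        s, t = net.labels[0], net.labels[-1]
        small = suboptimal_paths(net, s, t, delta=0.2, max_paths=10000)
        large = suboptimal_paths(net, s, t, delta=0.8, max_paths=10000)
        assert {tuple(p) for p, _ in small.suboptimal} <= {
            tuple(p) for p, _ in large.suboptimal
        }

    def test_truncation_flag(self):
        net = random_network(n_nodes=9, edge_prob=0.6, seed=11)
        s, t = net.labels[0], net.labels[-1]
        full = suboptimal_paths(net, s, t, delta=2.0, max_paths=10000)
        if len(full.suboptimal) > 2:
            cut = suboptimal_paths(net, s, t, delta=2.0, max_paths=2)
            assert cut.truncated
            assert len(cut.suboptimal) == 2


class TestEdgePathUsage:
    def test_single_path(self):
        net = simple_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        ps = suboptimal_paths(net, "A", "C", delta=0.0)
        usage = edge_path_usage(ps)
        assert usage == {("A", "B"): 1, ("B", "C"): 1}

    def test_triangle_all_edges_once(self):
        net = simple_network([("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.0)])
        ps = suboptimal_paths(net, "A", "C", delta=1.5)
        usage = edge_path_usage(ps)
        assert usage == {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1}

    def test_counts_sum_to_total_edges_in_paths(self):
        net = random_network(n_nodes=8, edge_prob=0.5, seed=5)
        s, t = net.labels[0], net.labels[-1]
        ps = suboptimal_paths(net, s, t, delta=1.0, max_paths=10000)
        usage = edge_path_usage(ps)
        assert sum(usage.values()) == sum(len(p) - 1 for p, _ in ps.suboptimal)


@pytest.fixture(scope="module")
def analysis():
    spec = TwoLobeMechanismSpec(n_frames=300, seed=5)
    traj, layout = generate_two_lobe_trajectory(spec)
    aligned = align_trajectory(traj)
    nm = identity_node_map(traj.n_atoms)
    corr = dccm(aligned, nm)
    contacts = contact_persistence(traj, nm, cutoff=4.5)
    net = build_network(contacts, corr, persistence_min=0.75,
                        exclude_neighbors=0)
    part = girvan_newman(net)
    prof = betweenness(net)
    return net, layout, part, prof, nm


class TestEndToEndTwoLobe:
    def test_communities_split_along_lobes(self, analysis):
        net, layout, part, _, nm = analysis
        assert part.n_communities >= 2
        a_comms = {part.community_of[nm.labels[i]] for i in layout.lobe_a}
        b_comms = {part.community_of[nm.labels[i]] for i in layout.lobe_b}
        assert a_comms.isdisjoint(b_comms)

    def test_critical_nodes_on_planted_bridge(self, analysis):
        net, layout, part, prof, nm = analysis
        crit = critical_nodes(net, part, prof)
        crit_idx = {nm.labels.index(c) for c in crit}
        assert crit_idx
        assert crit_idx <= set(layout.connectors)

    def test_all_paths_cross_bridge(self, analysis):
        net, layout, part, prof, nm = analysis
        s = nm.labels[layout.lobe_a[1]]
        t = nm.labels[layout.lobe_b[1]]
        ps = suboptimal_paths(net, s, t, max_paths=5000)
        conn = {nm.labels[i] for i in layout.connectors}
        usage = edge_path_usage(ps)
        for p, _ in ps.suboptimal:
            assert any(u in conn and v in conn for u, v in zip(p, p[1:]))
        assert any(u in conn and v in conn for u, v in usage)
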