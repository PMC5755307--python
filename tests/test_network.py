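import collections

import networkx as nx
import numpy as np
import pytest

from forumscope import network as net

from conftest import make_tables, random_digraph


def bfs_efficiency_oracle(graph):
    """Independent brute-force oracle: all-pairs BFS on the undirected view."""
    nodes = list(graph.nodes)
    und = {n: set() for n in nodes}
    for u, v in graph.edges:
        und[u].add(v)
        und[v].add(u)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for i, src in enumerate(nodes):
        dist = {src: 0}
        queue = collections.deque([src])
        while queue:
            cur = queue.popleft()
            for nbr in und[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + 1
                    queue.append(nbr)
        for tgt in nodes[i + 1 :]:
            if tgt in dist:
                total += 1.0 / dist[tgt]
    return 2.0 * total / (n * (n - 1))


class TestBuild:
    def test_comment_on_thread_creates_arc_to_opener(self):
        tables = make_tables(
            comments=[
                ("c1", "p1", 1, "u1", "opening", "2016-01-01 10:00"),
                ("c2", "p1", 2, "u2", "responding", "2016-01-01 11:00"),
            ],
        )
        g = net.build_interaction_network(tables)
        assert g["u2"]["u1"]["weight"] == 1
        assert not g.has_edge("u1", "u2")

    def test_repeated_replies_accumulate_weight(self):
        replies = [
            (f"r{i}", "c1", "u2", "u1", "t", "2016-01-01 10:00") for i in range(3)
        ]
        tables = make_tables(
            comments=[("c1", "p1", 1, "u1", "x", "2016-01-01 09:00")], replies=replies
        )
        g = net.build_interaction_network(tables)
        assert g["u2"]["u1"]["weight"] == 3

    def test_empty_tables_give_empty_graph(self):
        g = net.build_interaction_network(make_tables())
        assert g.number_of_nodes() == 0

    def test_self_interactions_discarded(self):
        tables = make_tables(
            comments=[
                ("c1", "p1", 1, "u1", "x", "2016-01-01 09:00"),
                ("c2", "p1", 2, "u1", "self follow-up", "2016-01-01 10:00"),
            ],
            replies=[("r1", "c1", "u1", "u1", "note to self", "2016-01-01 11:00")],
        )
        g = net.build_interaction_network(tables)
        assert g.number_of_edges() == 0


class TestEfficiency:
    def test_complete_graph_is_one(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        assert net.network_efficiency(g) == pytest.approx(1.0)

    def test_isolated_nodes_are_zero(self):
        g = nx.empty_graph(3, create_using=nx.DiGraph)
        assert net.network_efficiency(g) == 0.0

    def test_three_path(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert net.network_efficiency(g) == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_below_two_nodes_defined_zero(self):
        g = nx.DiGraph()
        g.add_node("a")
        assert net.network_efficiency(g) == 0.0

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = random_digraph(rng, int(rng.integers(2, 31)), float(rng.uniform(0.02, 0.5)))
            assert net.network_efficiency(g) == pytest.approx(bfs_efficiency_oracle(g), abs=1e-12)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_digraph(rng, 12, 0.1)
            before = net.network_efficiency(g)
            candidates = [
                (u, v) for u in g.nodes for v in g.nodes if u != v and not g.has_edge(u, v)
            ]
            if not candidates:
                continue
            u, v = candidates[int(rng.integers(len(candidates)))]
            g.add_edge(u, v, weight=1)
            assert net.network_efficiency(g) >= before - 1e-12


class TestDensity:
    def test_complete_directed_graph(self):
        g = nx.complete_graph(3, create_using=nx.DiGraph)
        assert net.network_density(g) == 1.0

    def test_no_arcs(self):
        assert net.network_density(nx.empty_graph(5, create_using=nx.DiGraph)) == 0.0

    def test_three_arcs_on_four_nodes(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "d")])
        assert net.network_density(g) == pytest.approx(0.25)

    def test_bounded_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_digraph(rng, int(rng.integers(2, 15)), float(rng.uniform(0, 1)))
            assert 0.0 <= net.network_density(g) <= 1.0


class TestComponents:
    def test_two_pairs(self):
        g = nx.DiGraph([("u1", "u2"), ("u3", "u4")])
        comps, largest = net.weakly_connected_components(g)
        assert sorted(len(c) for c in comps) == [2, 2]
        assert largest == {"u1", "u2"}  # tie broken by smallest member

    def test_edgeless_gives_singletons(self):
        g = nx.empty_graph(3, create_using=nx.DiGraph)
        comps, _ = net.weakly_connected_components(g)
        assert len(comps) == 3

    def test_chain_is_one_component(self):
        g = nx.DiGraph([("u1", "u2"), ("u2", "u3")])
        comps, largest = net.weakly_connected_components(g)
        assert comps == [{"u1", "u2", "u3"}] and largest == {"u1", "u2", "u3"}

    def test_components_partition_nodes(self):
        rng = np.random.default_rng(3)
        g = random_digraph(rng, 20, 0.05)
        comps, _ = net.weakly_connected_components(g)
        all_nodes = [n for c in comps for n in c]
        assert len(all_nodes) == len(set(all_nodes)) == g.number_of_nodes()


class TestDegrees:
    def test_star_total_degrees(self):
        g = nx.DiGraph([("c", "l1"), ("c", "l2"), ("c", "l3")])
        degrees, table = net.degree_sequence(g, mode="total")
        assert degrees["c"] == 3 and degrees["l1"] == 1
        assert table["n_nodes"].sum() == 4

    def test_empty_graph_all_zero(self):
        degrees, _ = net.degree_sequence(nx.empty_graph(4, create_using=nx.DiGraph))
        assert set(degrees.values()) == {0}

    def test_frequency_table_conserves_n(self):
        rng = np.random.default_rng(21)
        g = random_digraph(rng, 25, 0.1)
        for mode in ("in", "out", "total"):
            _, table = net.degree_sequence(g, mode=mode)
            assert table["n_nodes"].sum() == g.number_of_nodes()


def test_edgelist_roundtrip(tmp_path):
    g = nx.DiGraph()
    g.add_edge("a", "b", weight=2)
    g.add_edge("b", "c", weight=1)
    net.write_edgelist(g, tmp_path / "edges.txt")
    back = net.read_edgelist(tmp_path / "edges.txt")
    assert sorted(back.edges(data="weight")) == sorted(g.edges(data="weight"))
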