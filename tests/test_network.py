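"""Binding network construction, hubs, backbone and pathway suggestion."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netbinder.clustering import BindingMode
from netbinder.network import (
    build_network,
    destination_mode,
    extract_backbone,
    pm_distance_matrix,
    suggest_pathway,
)


def mode_at(pm_id, com, d_D=None, e_inter=0.0):
    com = np.asarray(com, dtype=float)
    return BindingMode(pm_id=pm_id, representative=pm_id, e_inter=e_inter,
                       d_D=float(np.linalg.norm(com)) if d_D is None else d_D,
                       com=com, members=[pm_id])


def modes_from_points(points):
    return [mode_at(i + 1, p) for i, p in enumerate(points)]


def cutoff_graph(points, cutoff=12.0):
    """Brute-force reference: pure inclusive-cutoff graph on COM distances."""
    g = nx.Graph()
    g.add_nodes_from(range(1, len(points) + 1))
    for i, j in itertools.combinations(range(len(points)), 2):
        d = np.linalg.norm(np.subtract(points[i], points[j]))
        if d <= cutoff:
            g.add_edge(i + 1, j + 1, weight=float(d))
    g.remove_nodes_from([n for n in list(g) if g.degree[n] == 0])
    return g


class TestDistanceMatrix:
    def test_single_mode(self):
        m = pm_distance_matrix([mode_at(1, (1, 2, 3))])
        assert m.shape == (1, 1) and m[0, 0] == 0.0

    def test_two_modes(self):
        m = pm_distance_matrix([mode_at(1, (0, 0, 0)), mode_at(2, (0, 0, 7))])
        assert m[0, 1] == pytest.approx(7.0) == m[1, 0]

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 30, size=(4, 3))
        m = pm_distance_matrix(modes_from_points(pts))
        for i in range(4):
            for j in range(4):
                assert m[i, j] == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]))


class TestBuildNetwork:
    def test_line_of_five(self):
        # x = 0, 5, 10, 15, 60: pairs within 12 Å connect; node 5 is isolated
        pts = [(0, 0, 0), (5, 0, 0), (10, 0, 0), (15, 0, 0), (60, 0, 0)]
        net = build_network(modes_from_points(pts))
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset(e) for e in [(1, 2), (1, 3), (2, 3), (2, 4), (3, 4)]}
        assert net.excluded_ids == [5]
        assert [net.degree(n) for n in (1, 2, 3, 4)] == [2, 3, 3, 2]
        assert net.hub_ids == []

    def test_star_hub(self):
        center = mode_at(1, (0, 0, 0))
        leaves = [mode_at(i + 2, 11 * np.asarray(ax))
                  for i, ax in enumerate(
                      [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                       (0, 0, 1), (0, 0, -1)])]
        net = build_network([center] + leaves)
        assert net.degree(1) == 6
        assert net.hub_ids == [1]
        # leaf-leaf separations (15.56 or 22 Å) exceed the cutoff
        assert net.n_edges == 6

    def test_disconnected_pair_all_excluded(self):
        net = build_network([mode_at(1, (0, 0, 0)), mode_at(2, (20, 0, 0))])
        assert net.n_nodes == 0 and net.excluded_ids == [1, 2]

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            build_network([mode_at(1, (0, 0, 0))], edge_cutoff=-1.0)

    def test_uncapped_equals_pure_cutoff_graph(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 26))
            pts = rng.uniform(0, 35, size=(n, 3))
            net = build_network(modes_from_points(pts), max_edges=None)
            ref = cutoff_graph(pts)
            assert nx.utils.graphs_equal(
                nx.Graph(net.graph.edges), nx.Graph(ref.edges))
            # hub rule: exactly degree > 4
            assert set(net.hub_ids) == {v for v in ref if ref.degree[v] > 4}

    def test_degree_cap_enforced(self, rng):
        pts = rng.uniform(0, 8, size=(30, 3))  # dense cloud, everything close
        net = build_network(modes_from_points(pts), max_edges=3)
        assert all(d <= 3 for _, d in net.graph.degree)

    def test_cap_keeps_nearest_neighbors(self):
        # node 1 has candidates at 3, 4 and 10 Å but may keep only two;
        # the 10 Å edge is the one dropped (union rule keeps 2-3 edge alive)
        pts = [(0, 0, 0), (3, 0, 0), (0, 4, 0), (10, 0, 0)]
        net = build_network(modes_from_points(pts), max_edges=2)
        assert net.degree(1) == 2
        assert not net.graph.has_edge(1, 4)

    def test_monotone_in_cutoff(self, rng):
        pts = rng.uniform(0, 30, size=(15, 3))
        small = build_network(modes_from_points(pts), edge_cutoff=8,
                              max_edges=None)
        large = build_network(modes_from_points(pts), edge_cutoff=14,
                              max_edges=None)
        assert set(small.graph.edges) <= set(large.graph.edges)

    def test_relabeling_and_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.uniform(0, 25, size=(12, 3))
        net = build_network(modes_from_points(pts))
        R = Rotation.random(random_state=rng).as_matrix()
        moved = [mode_at(i + 1, pts[i] @ R.T + [50, -3, 7], d_D=float(np.linalg.norm(pts[i])))
                 for i in range(12)]
        net2 = build_network(moved)
        assert set(net.graph.edges) == set(net2.graph.edges)
        assert net.hub_ids == net2.hub_ids

    def test_destination_node_option(self):
        pts = [(5, 0, 0), (10, 0, 0)]
        pms = modes_from_points(pts)
        with_d = build_network(pms + [destination_mode(np.zeros(3))])
        assert 0 in with_d.graph
        assert with_d.graph.nodes[0]["d_D"] == 0.0
        assert with_d.n_nodes == 3


class TestBackbone:
    def test_largest_hub_component(self):
        # hand-built graph: hubs a,b,c connected, hub d isolated among hubs
        g = nx.Graph()
        hubs = [1, 2, 3, 4]
        g.add_edges_from([(1, 2), (2, 3)])
        g.add_node(4)
        for n in g.nodes:
            g.nodes[n]["d_D"] = float(n)
        net_like = type("N", (), {"graph": g, "hub_ids": hubs})()
        bb = extract_backbone(net_like)
        assert set(bb.nodes) == {1, 2, 3}
        assert set(map(frozenset, bb.edges)) == {frozenset((1, 2)),
                                                 frozenset((2, 3))}

    def test_no_hubs_empty_backbone(self):
        pts = [(0, 0, 0), (5, 0, 0)]
        net = build_network(modes_from_points(pts))
        assert net.backbone.number_of_nodes() == 0

    def test_fully_connected_hubs(self, rng):
        pts = rng.uniform(0, 6, size=(8, 3))  # tight cloud: all pairs < 12
        net = build_network(modes_from_points(pts), max_edges=None)
        assert set(net.hub_ids) == set(net.graph.nodes)
        assert set(net.backbone.nodes) == set(net.graph.nodes)

    def test_backbone_is_connected_subset_of_hubs(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 30, size=(20, 3))
            net = build_network(modes_from_points(pts))
            assert set(net.backbone.nodes) <= set(net.hub_ids)
            if net.backbone.number_of_nodes():
                assert nx.is_connected(net.backbone)


class TestSuggestPathway:
    def test_chain_graph(self):
        pts = [(0, 0, 0), (8, 0, 0), (16, 0, 0), (24, 0, 0)]
        net = build_network(modes_from_points(pts))
        table = suggest_pathway(net, source=1, sink=4)
        assert list(table.pm_id) == [1, 2, 3, 4]

    def test_shortest_total_length_route(self):
        # two routes from 1 to 5: via 2-3 (total 14) or via 4 (total 18)
        g = nx.Graph()
        for n, d in [(1, 20.0), (2, 15.0), (3, 10.0), (4, 12.0), (5, 0.0)]:
            g.add_node(n, d_D=d, is_hub=False, in_backbone=False)
        g.add_weighted_edges_from(
            [(1, 2, 5), (2, 3, 4), (3, 5, 5), (1, 4, 9), (4, 5, 9)])
        # exhaustive enumeration oracle
        best = min(
            (p for p in nx.all_simple_paths(g, 1, 5)),
            key=lambda p: sum(g.edges[a, b]["weight"] for a, b in zip(p, p[1:])))
        net_like = type("N", (), {"graph": g})()
        table = suggest_pathway(net_like, source=1, sink=5)
        assert list(table.pm_id) == best == [1, 2, 3, 5]

    def test_default_endpoints_by_d_D(self):
        pts = [(2, 0, 0), (10, 0, 0), (18, 0, 0)]
        net = build_network(modes_from_points(pts))
        table = suggest_pathway(net)
        assert table.pm_id.iloc[0] == 3   # largest d_D
        assert table.pm_id.iloc[-1] == 1  # smallest d_D

    def test_disconnected_endpoints_raise(self):
        pts = [(0, 0, 0), (5, 0, 0), (40, 0, 0), (45, 0, 0)]
        net = build_network(modes_from_points(pts))
        with pytest.raises(nx.NetworkXNoPath):
            suggest_pathway(net, source=1, sink=4)
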