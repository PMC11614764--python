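"""Node features vs brute-force graph oracles; KP, keystone calls, clustering."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from keystonenet.metrics import (
    ClusterAssignment,
    call_keystones,
    cluster_positive_network,
    keystone_potential,
    network_summary,
    node_features,
)

from conftest import make_network


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx's centrality implementations)
# ---------------------------------------------------------------------------


def _all_shortest_paths(g, s, t):
    """Enumerate all shortest s-t paths by BFS layering."""
    if s == t:
        return []
    dist = {s: 0}
    parents = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    if t not in dist:
        return []
    paths = []

    def backtrack(v, acc):
        if v == s:
            paths.append(list(reversed(acc + [s])))
            return
        for p in parents[v]:
            backtrack(p, acc + [v])

    backtrack(t, [])
    return paths


def brute_betweenness(g):
    bc = {n: 0.0 for n in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for path in paths:
            for interior in path[1:-1]:
                bc[interior] += 1.0 / len(paths)
    return bc


def brute_local_transitivity(g, node):
    nbrs = list(g.neighbors(node))
    if len(nbrs) < 2:
        return None
    closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
    return closed / math.comb(len(nbrs), 2)


def brute_vertex_connectivity(g):
    n = g.number_of_nodes()
    if nx.density(g) == 1.0:
        return n - 1
    for k in range(n - 1):
        for removal in itertools.combinations(g.nodes, k):
            h = g.copy()
            h.remove_nodes_from(removal)
            if h.number_of_nodes() <= 1 or not nx.is_connected(h):
                return k
    return n - 1


class TestNodeFeatures:
    def test_triangle_closed_forms(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        feats = node_features(net)
        for f in feats.values():
            assert f.nd == pytest.approx(2 / 3)
            assert f.t == pytest.approx(1.0)
            assert f.bc == pytest.approx(0.0)

    def test_star_closed_forms(self):
        net = make_network([("hub", leaf, 0.5) for leaf in "wxyz"])
        feats = node_features(net)
        assert feats["hub"].bc == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert feats["hub"].t == pytest.approx(0.0)
        assert feats["w"].bc == pytest.approx(0.0)
        assert not feats["w"].t_defined and math.isnan(feats["w"].t)

    def test_negative_edges_count_in_topology(self):
        # feature topology ignores the sign of mean_rho
        net = make_network([("a", "b", -0.5), ("b", "c", 0.5)])
        feats = node_features(net)
        assert feats["b"].degree == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graph_matches_brute_force(self, seed):
        g = nx.gnp_random_graph(12, 0.35, seed=seed)
        net = make_network(
            [(str(u), str(v), 0.5) for u, v in g.edges],
            nodes=[str(n) for n in g.nodes],
        )
        feats = node_features(net)
        h = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        bc_oracle = brute_betweenness(h)
        for node, f in feats.items():
            assert f.bc == pytest.approx(bc_oracle[node], abs=1e-9)
            assert f.nd == pytest.approx(h.degree(node) / 12)
            t_oracle = brute_local_transitivity(h, node)
            if t_oracle is None:
                assert not f.t_defined
            else:
                assert f.t == pytest.approx(t_oracle)


class TestKeystonePotential:
    def test_arithmetic(self):
        net = make_network([("a", "b", 0.5)])
        feats = node_features(net)
        f = feats["a"]
        f.degree, f.nd, f.t, f.t_defined, f.bc = 3, 0.3, 0.8, True, 1.2
        feats["b"].bc = 0.5  # some positive bc exists
        kps = keystone_potential(feats)
        assert kps["a"] == pytest.approx(0.2)

    def test_degree_below_two_gives_zero(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)], nodes="abcd")
        net.graph.add_edge("c", "d", mean_rho=0.5, support=1)  # d has degree 1
        kps = keystone_potential(node_features(net))
        assert kps["d"] == 0.0

    def test_bc_floor_rule(self):
        # node with bc=0, t=1, nd=0.4 in a network whose min positive bc is 2
        net = make_network([("a", "b", 0.5)])
        feats = node_features(net)
        fa, fb = feats["a"], feats["b"]
        fa.nd, fa.t, fa.t_defined, fa.bc = 0.4, 1.0, True, 0.0
        fb.nd, fb.t, fb.t_defined, fb.bc = 0.5, 0.5, True, 2.0
        kps = keystone_potential(feats)
        assert kps["a"] == pytest.approx(0.4 / 1.0)

    def test_all_zero_bc_gives_zero_kp(self):
        net = make_network([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        kps = keystone_potential(node_features(net))  # triangle: all bc = 0
        assert all(v == 0.0 for v in kps.values())

    def test_scale_equivariance_under_bc_scaling(self):
        net = make_network([("a", "b", 0.5)])
        feats = {}
        rng = np.random.default_rng(0)
        for i in range(6):
            f = node_features(net)["a"]
            f.taxon = f"t{i}"
            f.nd, f.t, f.t_defined = rng.uniform(0.1, 1), rng.uniform(0.1, 1), True
            f.bc = float(rng.uniform(0, 3)) if i % 2 else 0.0
            feats[f.taxon] = f
        kp1 = keystone_potential({k: v for k, v in feats.items()})
        for f in feats.values():
            f.bc *= 4.0
        kp2 = keystone_potential(feats)
        for k in kp1:
            assert kp2[k] == pytest.approx(kp1[k] / 4.0)


class TestCallKeystones:
    def test_worked_example(self):
        kps = {f"t{i}": v for i, v in enumerate([1, 2, 3, 4, 100])}
        calls = call_keystones(kps, mad_factor=5)
        assert calls.cutoff == pytest.approx(8.0)  # median 3 + 5 * MAD 1
        assert calls.keystones == ["t4"]

    def test_constant_kps_yield_no_keystones(self):
        calls = call_keystones({f"t{i}": 2.5 for i in range(10)})
        assert calls.cutoff == pytest.approx(2.5)
        assert calls.keystones == []

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(5.0, 1.0, size=195)  # right-skewed bulk
        med = np.median(values)
        kps = {f"t{i}": v for i, v in enumerate(values)}
        for i in range(5):
            kps[f"planted{i}"] = 50 * med
        calls = call_keystones(kps, mad_factor=5)
        assert sorted(calls.keystones) == sorted(f"planted{i}" for i in range(5))

    def test_order_invariance_and_mad_monotonicity(self):
        rng = np.random.default_rng(1)
        kps = {f"t{i}": float(v) for i, v in enumerate(rng.exponential(1, 50))}
        shuffled = dict(reversed(list(kps.items())))
        assert call_keystones(kps).cutoff == call_keystones(shuffled).cutoff
        cuts = [call_keystones(kps, mad_factor=f).cutoff for f in (1, 3, 5, 8)]
        assert cuts == sorted(cuts)


class TestSummaryAndClusters:
    def test_two_triangle_modularity(self):
        net = make_network(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0)]
        )
        partition = ClusterAssignment(
            {"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1}, 2
        )
        summary = network_summary(net, partition)
        assert summary.modularity == pytest.approx(0.5)

    def test_k4_cohesion_and_cut_vertex(self):
        k4 = make_network(
            [(u, v, 0.5) for u, v in itertools.combinations("abcd", 2)]
        )
        part = ClusterAssignment({n: 0 for n in "abcd"}, 1)
        assert network_summary(k4, part).cohesion == 3
        chain = make_network([("a", "b", 0.5), ("b", "c", 0.5)])  # b is a cut vertex
        part2 = ClusterAssignment({n: 0 for n in "abc"}, 1)
        assert network_summary(chain, part2).cohesion == 1

    @pytest.mark.parametrize("seed", [0, 3])
    def test_cohesion_matches_brute_force(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        net = make_network([(str(u), str(v), 0.5) for u, v in g.edges])
        part = ClusterAssignment({str(n): 0 for n in g.nodes}, 1)
        h = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        assert network_summary(net, part).cohesion == brute_vertex_connectivity(h)

    def test_one_cluster_modularity_nonpositive(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            net = make_network(
                [(str(u), str(v), float(rng.uniform(0.1, 1))) for u, v in g.edges],
                nodes=[str(n) for n in g.nodes],
            )
            part = ClusterAssignment({str(n): 0 for n in g.nodes}, 1)
            assert network_summary(net, part).modularity <= 1e-12

    def test_two_clique_clusters(self):
        edges = [(u, v, 0.8) for u, v in itertools.combinations("abcde", 2)]
        edges += [(u, v, 0.8) for u, v in itertools.combinations("vwxyz", 2)]
        edges.append(("a", "v", 0.1))
        clusters = cluster_positive_network(make_network(edges))
        assert clusters.n_clusters == 2
        groups = {frozenset(clusters.members(c)) for c in range(2)}
        assert groups == {frozenset("abcde"), frozenset("vwxyz")}

    def test_edgeless_network_singletons(self):
        net = make_network([], nodes="abcd")
        clusters = cluster_positive_network(net)
        assert clusters.n_clusters == 4
        assert sorted(clusters.assignments) == list("abcd")

    def test_negative_edges_ignored_for_clustering(self):
        net = make_network([("a", "b", -0.9), ("c", "d", 0.9)])
        clusters = cluster_positive_network(net)
        assert clusters.assignments["c"] == clusters.assignments["d"]
        assert clusters.assignments["a"] != clusters.assignments["b"]

    def test_weighted_planted_partition_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            nodes = [f"n{i}" for i in range(20)]
            truth = {n: i // 10 for i, n in enumerate(nodes)}
            edges = []
            for u, v in itertools.combinations(nodes, 2):
                if truth[u] == truth[v]:
                    w = rng.normal(0.6, 0.1)
                else:
                    if rng.random() > 0.5:
                        continue
                    w = rng.normal(0.05, 0.02)
                if w > 0:
                    edges.append((u, v, float(w)))
            clusters = cluster_positive_network(make_network(edges, nodes=nodes))
            pred = [clusters.assignments[n] for n in nodes]
            if adjusted_rand_score([truth[n] for n in nodes], pred) >= 0.9:
                hits += 1
        assert hits >= 9
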