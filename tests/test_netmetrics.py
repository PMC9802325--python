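"""Graph statistics against closed forms, brute-force oracles, and networkx
cross-checks."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from trabnet import (char_path_length, clustering_coefficient, compute_all,
                     count_components, edge_length_stats, mean_clustering,
                     random_reference, simplify, small_worldness)
from trabnet.graphx import Edge, NetworkGraph, Vertex


def random_graph(n, p, seed):
    return nx.gnp_random_graph(n, p, seed=seed)


def brute_clustering(g, v):
    nbrs = list(g[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    e = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
    return 2 * e / (k * (k - 1))


class TestSimplify:
    def _net(self, vertices, edges):
        vs = tuple(Vertex(i, (0.0, float(i)), "junction", ()) for i in range(vertices))
        es = tuple(Edge(i, a, b, ((0, 0), (0, 1)), 20.5) for i, (a, b) in enumerate(edges))
        return NetworkGraph(vs, es, 20.5)

    def test_self_loop_dropped(self):
        s = simplify(self._net(1, [(0, 0)]))
        assert s.number_of_nodes() == 1 and s.number_of_edges() == 0

    def test_parallel_edges_collapse(self):
        s = simplify(self._net(2, [(0, 1)] * 3))
        assert s.number_of_edges() == 1

    def test_mixed_multigraph_counts_distinct_pairs(self):
        edges = [(0, 1), (0, 1), (1, 2), (2, 2), (3, 4), (4, 3), (0, 3)]
        s = simplify(self._net(5, edges))
        distinct = {tuple(sorted(e)) for e in edges if e[0] != e[1]}
        assert s.number_of_edges() == len(distinct)
        assert s.number_of_nodes() == 5


class TestClustering:
    def test_triangle_vertex(self):
        assert clustering_coefficient(nx.complete_graph(3), 0) == 1.0

    def test_path_middle_vertex(self):
        assert clustering_coefficient(nx.path_graph(3), 1) == 0.0

    def test_hub_graph_closed_form(self):
        g = nx.Graph([("hub", "a"), ("hub", "b"), ("hub", "c"), ("a", "b")])
        assert clustering_coefficient(g, "hub") == pytest.approx(1 / 3)
        assert mean_clustering(g) == pytest.approx((1 / 3 + 1 + 1 + 0) / 4)

    def test_missing_vertex_raises(self):
        with pytest.raises(KeyError):
            clustering_coefficient(nx.path_graph(3), 99)

    def test_star_graph_zero(self):
        assert mean_clustering(nx.star_graph(3)) == 0.0

    def test_matches_brute_force_and_networkx(self):
        for seed in range(30):
            g = random_graph(12, 0.3, seed)
            for v in g:
                c = clustering_coefficient(g, v)
                assert c == pytest.approx(brute_clustering(g, v), abs=1e-12)
            assert mean_clustering(g) == pytest.approx(
                nx.average_clustering(g, count_zeros=True), abs=1e-12)


class TestCharPathLength:
    def test_complete_graph(self):
        assert char_path_length(nx.complete_graph(3)) == 1.0

    def test_three_vertex_path(self):
        assert char_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_edgeless_graph_flagged(self):
        g = nx.empty_graph(5)
        assert math.isnan(char_path_length(g))

    def test_matches_all_pairs_bfs_oracle(self):
        for seed in range(20):
            g = random_graph(10, 0.4, seed)
            comps = [c for c in nx.connected_components(g) if len(c) >= 2]
            if not comps:
                continue
            largest = g.subgraph(max(comps, key=len))
            dists = dict(nx.all_pairs_shortest_path_length(largest))
            pairs = [dists[u][v] for u, v in combinations(largest.nodes, 2)]
            assert char_path_length(g) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_weighted_option_averages_components(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        # components contribute (4/3 over 3 pairs) and (1 over 1 pair)
        expected = (4 + 1) / 4
        assert char_path_length(g, component="weighted") == pytest.approx(expected)


class TestComponentsAndLengths:
    def _net(self, n_vertices, edges):
        vs = tuple(Vertex(i, (0.0, float(i)), "junction", ()) for i in range(n_vertices))
        es = tuple(Edge(i, a, b, ((0, 0), (0, 1)), float(l))
                   for i, (a, b, l) in enumerate(edges))
        return NetworkGraph(vs, es, 20.5)

    def test_empty_graph_zero_components(self):
        assert count_components(self._net(0, [])) == 0

    def test_two_disjoint_triangles(self):
        edges = [(0, 1, 1), (1, 2, 1), (2, 0, 1), (3, 4, 1), (4, 5, 1), (5, 3, 1)]
        assert count_components(self._net(6, edges)) == 2

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 30
            edges = [(int(a), int(b), 1.0)
                     for a, b in rng.integers(0, n, size=(25, 2))]
            net = self._net(n, edges)
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b, _ in edges:
                parent[find(a)] = find(b)
            assert count_components(net) == len({find(i) for i in range(n)})

    def test_edge_length_stats(self):
        net = self._net(2, [(0, 1, 205.0)])
        mean, sd, _ = edge_length_stats(net)
        assert mean == 205.0 and sd == 0.0
        net2 = self._net(2, [(0, 1, 100.0), (0, 1, 300.0)])
        mean2, sd2, hist = edge_length_stats(net2)
        assert mean2 == 200.0
        assert sd2 == pytest.approx(np.std([100, 300], ddof=1))
        assert hist is not None

    def test_no_edges_flagged(self):
        mean, sd, hist = edge_length_stats(self._net(3, []))
        assert math.isnan(mean) and math.isnan(sd) and hist is None


class TestRandomReference:
    def test_unique_graphs_k3_k4(self):
        assert random_reference(3, 3, n_samples=5, seed=1) == (1.0, 1.0)
        assert random_reference(4, 6, n_samples=5, seed=1) == (1.0, 1.0)

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            random_reference(4, 7)

    def test_deterministic_under_seed(self):
        assert random_reference(15, 30, seed=9) == random_reference(15, 30, seed=9)

    def test_within_three_se_of_large_oracle_run(self):
        # independent large-sample estimate of E[C] for G(20, 40)
        rng = np.random.default_rng(123)
        cs = [nx.average_clustering(nx.gnm_random_graph(20, 40, seed=int(s)))
              for s in rng.integers(2**31, size=2000)]
        mu, se = np.mean(cs), np.std(cs, ddof=1) / np.sqrt(len(cs))
        c_r, _ = random_reference(20, 40, n_samples=200, seed=4)
        se_ours = np.std(cs, ddof=1) / np.sqrt(200)
        assert abs(c_r - mu) < 3 * (se + se_ours)


class TestSmallWorldness:
    def test_complete_graph_sigma_one(self):
        sigma, c_r, l_r = small_worldness(nx.complete_graph(4), n_samples=5, seed=0)
        assert sigma == 1.0 and c_r == 1.0 and l_r == 1.0

    def test_ring_lattice_is_small_world_like(self):
        g = nx.watts_strogatz_graph(20, 4, p=0.1, seed=2)
        sigma, _, _ = small_worldness(g, n_samples=50, seed=3)
        assert sigma > 1.0

    def test_undefined_flagged_not_zero(self):
        g = nx.empty_graph(3)
        g.add_edge(0, 1)
        sigma, c_r, l_r = small_worldness(g, n_samples=5, seed=0)
        assert math.isnan(sigma)  # C_r = 0 for 3 vertices, 1 edge


class TestComputeAll:
    def test_empty_graph_counts_zero_rest_flagged(self):
        rec = compute_all(NetworkGraph((), (), 20.5))
        assert rec.n_vertices == 0 and rec.n_edges == 0 and rec.n_components == 0
        assert math.isnan(rec.mean_clustering) and math.isnan(rec.sigma)

    def test_two_disjoint_triangles_closed_form(self):
        vs = tuple(Vertex(i, (0.0, float(i)), "junction", ()) for i in range(6))
        pairs = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
        es = tuple(Edge(i, a, b, ((0, 0), (0, 1)), 20.5)
                   for i, (a, b) in enumerate(pairs))
        rec = compute_all(NetworkGraph(vs, es, 20.5), seed=1)
        assert rec.n_vertices == 6 and rec.n_edges == 6 and rec.n_components == 2
        assert rec.mean_clustering == 1.0 and rec.char_path_length == 1.0

    def test_composition_matches_individual_operations(self, thin_phantom,
                                                       clean_extraction):
        from trabnet import extract_network
        img, _ = thin_phantom
        g = extract_network(img, clean_extraction)
        rec = compute_all(g, depth_index=5, seed=42)
        simple = simplify(g)
        assert rec.n_vertices == g.n_vertices
        assert rec.mean_clustering == pytest.approx(mean_clustering(simple))
        assert rec.char_path_length == pytest.approx(char_path_length(simple))
        assert rec.mean_edge_length_um == pytest.approx(edge_length_stats(g)[0])
        assert rec.depth_index == 5

    def test_bounds_on_random_graphs(self):
        for seed in range(20):
            g = random_graph(12, 0.25, seed)
            c = mean_clustering(g)
            assert 0.0 <= c <= 1.0
            l = char_path_length(g)
            assert math.isnan(l) or l >= 1.0


class TestPhantomGroupContrast:
    def test_hoa_like_regime_has_more_components_and_shorter_edges(self):
        """Denser, thicker, more fragmented lattices yield more vertices and
        components and shorter struts than control-like lattices (group
        means over 10 seeded samples per regime)."""
        import dataclasses

        from trabnet import ExtractionParams, PhantomSpec, extract_network
        from trabnet import generate_slice

        params = ExtractionParams(min_object_px=10, min_hole_px=10)

        def group(spec, n=10):
            comps, lens, verts = [], [], []
            for i in range(n):
                img, _ = generate_slice(
                    dataclasses.replace(spec, rng_seed=spec.rng_seed + i), 0)
                g = extract_network(img, params)
                comps.append(count_components(g))
                verts.append(g.n_vertices)
                lens.append(edge_length_stats(g)[0])
            return np.mean(verts), np.mean(comps), np.nanmean(lens)

        ctrl = PhantomSpec(image_size=256, seed_points=40, strut_thickness_px=2,
                           fragmentation_prob=0.0, noise_sigma=0.05, rng_seed=1)
        hoa = PhantomSpec(image_size=256, seed_points=80, strut_thickness_px=4,
                          fragmentation_prob=0.25, noise_sigma=0.05, rng_seed=501)
        v_c, comp_c, len_c = group(ctrl)
        v_h, comp_h, len_h = group(hoa)
        assert v_h > v_c
        assert comp_h > comp_c
        assert len_h < len_c
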