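"""Per-network graph statistics: counts, clustering, characteristic path
length, edge-length statistics, and small-worldness.

Definitions follow the standard small-world formalism. For a vertex n_i with
k_i neighbors in a simple undirected graph, the clustering coefficient is
C_i = 2 E_i / (k_i (k_i - 1)) with E_i the number of edges among the
neighbors; the network value C is the arithmetic mean of C_i (vertices with
k_i < 2 contribute 0). The characteristic path length L is the mean
unweighted shortest-path distance (number of edges traversed) over all
unordered vertex pairs; on disconnected graphs — which fragmented trabecular
networks routinely are — L is computed within the largest connected
component. Small-worldness is sigma = (C / C_r) / (L / L_r), where C_r and
L_r come from equivalent uniform random graphs G(N, E) with matched vertex
and edge counts.

Undefined quantities (e.g. L of an edgeless graph, sigma when C_r = 0) are
returned as NaN — an explicit flag that serializes to null, never to 0.

The clustering and path-length kernels are implemented directly from the
definitions above (neighbor-set intersection; breadth-first search) so that
library routines can serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graphx import NetworkGraph


@dataclass(frozen=True)
class MetricsRecord:
    """Graph statistics for one slice. NaN marks undefined values."""

    n_vertices: int
    n_edges: int
    n_components: int
    mean_clustering: float
    char_path_length: float
    mean_edge_length_um: float
    sigma: float
    c_rand: float
    l_rand: float
    depth_index: int = 0

    FIELDS = ("n_vertices", "n_edges", "n_components", "mean_clustering",
              "char_path_length", "mean_edge_length_um", "sigma",
              "c_rand", "l_rand", "depth_index")

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def simplify(g: NetworkGraph | nx.Graph) -> nx.Graph:
    """Simple undirected view: drop self-loops, collapse parallel edges.

    The vertex set is unchanged; the clustering/path-length formulas assume a
    simple graph.
    """
    if isinstance(g, NetworkGraph):
        g = g.to_networkx()
    simple = nx.Graph(g)
    simple.remove_edges_from(nx.selfloop_edges(simple))
    return simple


def clustering_coefficient(g: nx.Graph, vertex) -> float:
    """C_i = 2 E_i / (k_i (k_i - 1)); 0 by convention when k_i < 2."""
    if vertex not in g:
        raise KeyError(f"vertex {vertex!r} not in graph")
    nbrs = set(g[vertex]) - {vertex}
    k = len(nbrs)
    if k < 2:
        return 0.0
    e_i = sum(1 for u in nbrs for v in g[u] if v in nbrs) // 2
    return 2.0 * e_i / (k * (k - 1))


def mean_clustering(g: nx.Graph) -> float:
    """Arithmetic mean of C_i over all vertices; NaN on the empty graph."""
    if g.number_of_nodes() == 0:
        return math.nan
    return sum(clustering_coefficient(g, v) for v in g) / g.number_of_nodes()


def _bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def char_path_length(g: nx.Graph, component: str = "largest") -> float:
    """Mean BFS shortest-path length over unordered vertex pairs.

    ``component="largest"`` (default) restricts to the largest connected
    component; ``"weighted"`` averages per-component values weighted by the
    number of pairs in each component. NaN when no component has >= 2
    vertices.
    """
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        return math.nan
    comps = [c for c in nx.connected_components(g) if len(c) >= 2]
    if not comps:
        return math.nan
    if component == "largest":
        comps = [max(comps, key=len)]
    elif component != "weighted":
        raise ValueError("component must be 'largest' or 'weighted'")
    total, n_pairs = 0.0, 0
    for comp in comps:
        sub = g.subgraph(comp)
        for u in comp:
            d = _bfs_distances(sub, u)
            total += sum(d.values())
            n_pairs += len(d) - 1
    return total / n_pairs  # each pair counted twice in both numerator & count


def count_components(g: NetworkGraph | nx.Graph) -> int:
    """Connected components; isolated vertices count; empty graph -> 0."""
    if isinstance(g, NetworkGraph):
        g = g.to_networkx()
    return nx.number_connected_components(g)


def edge_length_stats(g: NetworkGraph, bins: int = 20):
    """(mean, sample SD, histogram) of physical edge lengths, loops included.

    Returns ``(nan, nan, None)`` when the network has no edges.
    """
    lengths = np.array([e.length_um for e in g.edges], float)
    if lengths.size == 0:
        return math.nan, math.nan, None
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    hist = np.histogram(lengths, bins=bins)
    return float(lengths.mean()), sd, hist


def random_reference(n_vertices: int, n_edges: int, n_samples: int = 20,
                     seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """(C_r, L_r) of the G(N, E) equivalent-random-network ensemble.

    Samples uniform random simple graphs with exactly ``n_vertices`` and
    ``n_edges`` and averages mean clustering and characteristic path length
    (largest component) across samples. Deterministic under ``seed``.
    """
    max_edges = n_vertices * (n_vertices - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_vertices} vertices")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cs, ls = [], []
    for _ in range(n_samples):
        sample = nx.gnm_random_graph(n_vertices, n_edges,
                                     seed=int(rng.integers(2**31)))
        cs.append(mean_clustering(sample))
        ls.append(char_path_length(sample))
    return float(np.nanmean(cs)), float(np.nanmean(ls))


def small_worldness(g: nx.Graph, n_samples: int = 20, seed: int = 0) -> tuple[float, float, float]:
    """sigma = (C/C_r) / (L/L_r) against the matched G(N, E) ensemble.

    Returns ``(sigma, C_r, L_r)``; sigma is NaN when C, L, C_r or L_r is
    undefined or zero.
    """
    c = mean_clustering(g)
    l = char_path_length(g)
    c_r, l_r = random_reference(g.number_of_nodes(), g.number_of_edges(),
                                n_samples=n_samples, seed=seed)
    if any(math.isnan(x) for x in (c, l, c_r, l_r)) or c_r == 0 or l == 0:
        return math.nan, c_r, l_r
    return (c / c_r) / (l / l_r), c_r, l_r


def compute_all(g: NetworkGraph, depth_index: int = 0, seed: int = 0,
                n_reference_samples: int = 20) -> MetricsRecord:
    """Populate a full MetricsRecord for one extracted network."""
    multi = g.to_networkx()
    simple = simplify(multi)
    c = mean_clustering(simple)
    l = char_path_length(simple)
    mean_len, _, _ = edge_length_stats(g)
    if simple.number_of_nodes() >= 2 and simple.number_of_edges() >= 1:
        sigma, c_r, l_r = small_worldness(simple, n_samples=n_reference_samples, seed=seed)
    else:
        sigma, c_r, l_r = math.nan, math.nan, math.nan
    return MetricsRecord(
        n_vertices=g.n_vertices,
        n_edges=g.n_edges,
        n_components=count_components(multi),
        mean_clustering=c,
        char_path_length=l,
        mean_edge_length_um=mean_len,
        sigma=sigma,
        c_rand=c_r,
        l_rand=l_r,
        depth_index=depth_index,
    )
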