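"""Component decomposition and per-network / per-word descriptive measures.

Terminology follows the cognitive-network-science literature: the *giant
component* is the connected component with the most nodes, *lexical islands*
are all other components of at least two nodes, and *lexical hermits* are
isolated nodes. An edgeless network has no giant component (all nodes are
hermits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.stats

__all__ = [
    "ComponentSummary", "NetworkSummary", "DegenerateGraphError",
    "decompose", "giant_component", "density", "degree_stats",
    "assortativity", "heterogeneity", "clustering_coefficient",
    "average_clustering", "closeness_centrality", "closeness_all", "word_measures",
    "network_summary", "compare_groups", "aspl_and_diameter",
]


class DegenerateGraphError(ValueError):
    """A measure is undefined on this graph (e.g. zero degree variance)."""


@dataclass(frozen=True)
class ComponentSummary:
    """Giant / island / hermit decomposition of a network."""

    n: int
    giant_nodes: int
    island_nodes: int
    hermit_nodes: int
    island_count: int

    @property
    def giant_pct(self) -> float:
        return 100.0 * self.giant_nodes / self.n

    @property
    def island_pct(self) -> float:
        return 100.0 * self.island_nodes / self.n

    @property
    def hermit_pct(self) -> float:
        return 100.0 * self.hermit_nodes / self.n


def _components(network: nx.Graph) -> list[set]:
    return list(nx.connected_components(network))


def giant_component(network: nx.Graph) -> nx.Graph:
    """Subgraph on the largest component with >= 2 nodes.

    Ties on size are broken deterministically by the smallest node key.
    Raises :class:`DegenerateGraphError` on an edgeless network, which has
    no giant component under the hermit semantics used here.
    """
    comps = [c for c in _components(network) if len(c) >= 2]
    if not comps:
        raise DegenerateGraphError("network has no component with >= 2 nodes")
    giant = min(comps, key=lambda c: (-len(c), min(str(v) for v in c)))
    return network.subgraph(giant).copy()


def decompose(network: nx.Graph) -> ComponentSummary:
    """Partition the network into giant component, islands and hermits."""
    if network.number_of_nodes() < 1:
        raise ValueError("empty network")
    comps = _components(network)
    multi = [c for c in comps if len(c) >= 2]
    hermits = sum(1 for c in comps if len(c) == 1)
    if not multi:
        return ComponentSummary(network.number_of_nodes(), 0, 0, hermits, 0)
    giant = min(multi, key=lambda c: (-len(c), min(str(v) for v in c)))
    islands = [c for c in multi if c is not giant]
    return ComponentSummary(
        n=network.number_of_nodes(),
        giant_nodes=len(giant),
        island_nodes=sum(len(c) for c in islands),
        hermit_nodes=hermits,
        island_count=len(islands),
    )


def density(n: int, e: int) -> float:
    """Edge density 2E / (N(N-1)); requires N >= 2."""
    if n < 2:
        raise ValueError("density requires N >= 2")
    return 2.0 * e / (n * (n - 1))


def degree_stats(network: nx.Graph, scope: str = "whole") -> tuple[float, int, float]:
    """(mean, max, population SD) of degrees over the whole network or GC."""
    if scope == "whole":
        g = network
        if g.number_of_nodes() == 0:
            raise ValueError("empty network")
    elif scope == "giant":
        g = giant_component(network)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    return float(degrees.mean()), int(degrees.max()), float(degrees.std(ddof=0))


def assortativity(network: nx.Graph) -> float:
    """Degree assortativity: Pearson r of degrees over edge endpoints.

    Each undirected edge contributes both (k_u, k_v) and (k_v, k_u), so the
    correlation is symmetric (Newman's r). Raises
    :class:`DegenerateGraphError` when all endpoint degrees are equal.
    """
    if network.number_of_edges() == 0:
        raise ValueError("assortativity requires at least one edge")
    deg = dict(network.degree())
    xs, ys = [], []
    for u, v in network.edges:
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    sx = x.std(ddof=0)
    if sx == 0:
        raise DegenerateGraphError("all edge-endpoint degrees equal; assortativity undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * y.std(ddof=0)))


def heterogeneity(network: nx.Graph) -> float:
    """Estrada heterogeneity index, in [0, 1].

    Sum over edges of (k_i^(-1/2) - k_j^(-1/2))^2 normalized by
    N - 2*sqrt(N-1); 0 for regular graphs, 1 for a star.
    """
    n = network.number_of_nodes()
    if n < 3:
        raise ValueError("heterogeneity requires N >= 3")
    if network.number_of_edges() == 0:
        raise ValueError("heterogeneity requires at least one edge")
    deg = dict(network.degree())
    raw = sum(
        (deg[u] ** -0.5 - deg[v] ** -0.5) ** 2 for u, v in network.edges
    )
    return float(raw / (n - 2.0 * math.sqrt(n - 1)))


def clustering_coefficient(network: nx.Graph, node) -> float:
    """Local clustering: triangles through node / (k(k-1)/2); 0 for k < 2."""
    return float(nx.clustering(network, node))


def average_clustering(network: nx.Graph, scope: str = "whole") -> float:
    """Arithmetic mean of local clustering over the scope's nodes."""
    g = network if scope == "whole" else giant_component(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty scope")
    return float(nx.average_clustering(g))


def closeness_centrality(network: nx.Graph, node) -> float:
    """Component-scaled closeness: ((n_r-1)/sum d) * ((n_r-1)/(N-1)).

    ``n_r`` is the number of nodes reachable from ``node``; the second
    factor down-weights nodes in small components, so isolates score 0 and
    disconnected networks yield small values.
    """
    return float(nx.closeness_centrality(network, node, wf_improved=True))


def _gc_sparse(network: nx.Graph) -> tuple[sp.csr_matrix, list]:
    nodes = sorted(network.nodes, key=str)
    mat = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csr")
    return mat, nodes


def aspl_and_diameter(network: nx.Graph, chunk: int = 512) -> tuple[float, int]:
    """Average shortest path length and diameter of a connected graph.

    Runs chunked breadth-first searches through scipy's csgraph so that the
    full N x N distance matrix is never materialized.
    """
    if network.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if not nx.is_connected(network):
        raise ValueError("graph is not connected")
    mat, nodes = _gc_sparse(network)
    n = len(nodes)
    total = 0.0
    diam = 0
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        d = csgraph.shortest_path(mat, method="D", unweighted=True, indices=idx)
        total += d.sum()
        diam = max(diam, int(d.max()))
    return total / (n * (n - 1)), diam


def closeness_all(network: nx.Graph, chunk: int = 512) -> dict:
    """Component-scaled closeness for every node at once.

    Equivalent to calling :func:`closeness_centrality` per node but runs one
    chunked BFS sweep per connected component instead of one per node.
    """
    n_total = network.number_of_nodes()
    out = {}
    for comp in nx.connected_components(network):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        sub = network.subgraph(comp)
        mat, nodes = _gc_sparse(sub)
        nc = len(nodes)
        scale = (nc - 1) / (n_total - 1) if n_total > 1 else 1.0
        for start in range(0, nc, chunk):
            idx = np.arange(start, min(start + chunk, nc))
            d = csgraph.shortest_path(mat, method="D", unweighted=True, indices=idx)
            sums = d.sum(axis=1)
            for row, i in enumerate(idx):
                out[nodes[i]] = float((nc - 1) / sums[row] * scale)
    return out


def word_measures(network: nx.Graph, nodes=None) -> "pd.DataFrame":
    """Per-word measures: degree, clustering, closeness, length, log10 freq.

    ``length`` and ``log10_frequency`` come from node attributes set at
    build time; they are NaN when the attribute is absent or the frequency
    is zero.
    """
    import pandas as pd

    if nodes is None:
        nodes = list(network.nodes)
    clustering = nx.clustering(network, nodes)
    closeness = closeness_all(network)
    rows = []
    for v in nodes:
        attrs = network.nodes[v]
        freq = attrs.get("frequency")
        rows.append(
            {
                "word": v,
                "degree": network.degree(v),
                "clustering": clustering[v],
                "closeness": closeness[v],
                "length": attrs.get("length", np.nan),
                "log10_frequency": math.log10(freq) if freq else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("word")


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network descriptive statistics (one report row per network)."""

    n: int
    e: int
    density: float
    components: ComponentSummary
    assortativity: float | None
    heterogeneity: float | None
    degree_mean: float
    degree_max: int
    degree_sd: float

    @property
    def n_gc(self) -> int:
        return self.components.giant_nodes


def network_summary(network: nx.Graph, degree_scope: str = "giant") -> NetworkSummary:
    """Summarize a network; degree stats over the giant component by default.

    Assortativity/heterogeneity are None when undefined (edgeless or
    degree-regular networks).
    """
    comps = decompose(network)
    try:
        assort = assortativity(network)
    except (ValueError, DegenerateGraphError):
        assort = None
    try:
        het = heterogeneity(network)
    except ValueError:
        het = None
    scope = degree_scope if comps.giant_nodes else "whole"
    mean, mx, sd = degree_stats(network, scope)
    return NetworkSummary(
        n=network.number_of_nodes(),
        e=network.number_of_edges(),
        density=density(network.number_of_nodes(), network.number_of_edges()),
        components=comps,
        assortativity=assort,
        heterogeneity=het,
        degree_mean=mean,
        degree_max=mx,
        degree_sd=sd,
    )


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    dof: float
    pvalue: float

    @property
    def direction(self) -> int:
        return 0 if self.statistic == 0 else (1 if self.statistic > 0 else -1)


def compare_groups(measures_a, measures_b) -> WelchResult:
    """Welch two-sample t-test (unequal variances) between two groups.

    Returns the signed statistic (positive when group a's mean is larger),
    the Welch-Satterthwaite degrees of freedom, and the two-sided p value.
    """
    a = np.asarray(measures_a, dtype=float)
    b = np.asarray(measures_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            raise ValueError(
                "zero variance in both groups with equal means: t undefined (0/0)"
            )
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return WelchResult(sign * math.inf, float(len(a) + len(b) - 2), 0.0)
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))
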