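"""L-Spar backbone extraction and original-vs-backbone comparison reports.

Local sparsification keeps, for each node of degree d, the ⌈d^s⌉ incident
edges whose endpoints have the highest neighborhood overlap (Jaccard
similarity of open neighborhoods); the backbone is the union of the edges
kept by either endpoint. The node set is untouched, so the isolate count is
preserved by construction, and s = 1 returns the original graph. Jaccard
similarities are computed exactly (the networks handled here are small
enough that the original algorithm's minhash approximation is unnecessary).

Community structure is summarized with a seeded Louvain modularity
partition; isolates form singleton communities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .descriptives import (
    WelchResult,
    aspl_and_diameter,
    average_clustering,
    compare_groups,
    decompose,
    giant_component,
    word_measures,
)

__all__ = [
    "BackboneConfig", "BackboneReport", "NetworkReportRow",
    "jaccard_similarity", "lspar_backbone", "communities",
    "backbone_comparison",
]


@dataclass(frozen=True)
class BackboneConfig:
    """L-Spar parameters: sparsification exponent and determinism controls."""

    s: float = 0.5
    community_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")


def jaccard_similarity(network: nx.Graph, node_i, node_j) -> float:
    """|N(i) ∩ N(j)| / |N(i) ∪ N(j)| over open neighborhoods; 0 if union empty."""
    ni = set(network.neighbors(node_i))
    nj = set(network.neighbors(node_j))
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def lspar_backbone(network: nx.Graph, config: BackboneConfig | float = 0.5) -> nx.Graph:
    """Extract the L-Spar backbone at sparsification exponent s.

    Every node marks its ⌈d^s⌉ highest-Jaccard incident edges (ties broken
    by lexicographic neighbor key, for reproducibility); the backbone keeps
    the union of marked edges and the full node set. Since ⌈d^0⌉ = 1, even
    s = 0 leaves every non-isolated node with at least one edge.
    """
    if not isinstance(config, BackboneConfig):
        config = BackboneConfig(s=float(config))
    s = config.s
    neighborhoods = {v: set(network.neighbors(v)) for v in network.nodes}
    sim: dict[frozenset, float] = {}
    for u, v in network.edges:
        nu, nv = neighborhoods[u], neighborhoods[v]
        union = len(nu | nv)
        sim[frozenset((u, v))] = len(nu & nv) / union if union else 0.0

    backbone = nx.Graph()
    backbone.add_nodes_from(network.nodes(data=True))
    for v in network.nodes:
        d = network.degree(v)
        if d == 0:
            continue
        quota = math.ceil(d**s)
        ranked = sorted(
            neighborhoods[v], key=lambda u: (-sim[frozenset((v, u))], str(u))
        )
        backbone.add_edges_from((v, u) for u in ranked[:quota])
    return backbone


def communities(network: nx.Graph, seed: int = 0):
    """Seeded Louvain modularity partition: (partition, Q, count).

    Isolates end up as singleton communities. An edgeless network returns
    all-singleton communities with Q = 0.0 by convention (modularity is
    undefined without edges).
    """
    if network.number_of_edges() == 0:
        parts = [{v} for v in network.nodes]
        return parts, 0.0, len(parts)
    parts = nx.community.louvain_communities(network, seed=seed)
    q = nx.community.modularity(network, parts)
    return parts, float(q), len(parts)


@dataclass(frozen=True)
class NetworkReportRow:
    """One column of the original-vs-backbone comparison (Table-2 shape)."""

    n: int
    e: int
    gc_nodes: int
    gc_nodes_pct: float
    gc_edges: int
    gc_edges_pct: float
    degree_mean: float
    degree_mean_gc: float
    diameter_gc: int
    aspl_gc: float
    island_count: int
    component_size_min: int
    component_size_max: int
    isolates: int
    isolates_pct: float
    avg_clustering: float
    n_communities: int
    modularity: float


def _report_row(network: nx.Graph, seed: int) -> NetworkReportRow:
    comps = decompose(network)
    gc = giant_component(network)
    gc_e = gc.number_of_edges()
    aspl, diam = aspl_and_diameter(gc)
    multi = [c for c in nx.connected_components(network) if len(c) >= 2]
    giant_set = min(multi, key=lambda c: (-len(c), min(str(v) for v in c)))
    sizes = [len(c) for c in multi if c is not giant_set]
    _, q, ncomm = communities(network, seed=seed)
    n, e = network.number_of_nodes(), network.number_of_edges()
    return NetworkReportRow(
        n=n,
        e=e,
        gc_nodes=comps.giant_nodes,
        gc_nodes_pct=100.0 * comps.giant_nodes / n,
        gc_edges=gc_e,
        gc_edges_pct=100.0 * gc_e / e if e else 0.0,
        degree_mean=2.0 * e / n,
        degree_mean_gc=2.0 * gc_e / comps.giant_nodes,
        diameter_gc=diam,
        aspl_gc=aspl,
        island_count=comps.island_count,
        component_size_min=min(sizes) if sizes else comps.giant_nodes,
        component_size_max=max(sizes) if sizes else comps.giant_nodes,
        isolates=comps.hermit_nodes,
        isolates_pct=100.0 * comps.hermit_nodes / n,
        avg_clustering=average_clustering(network, scope="whole"),
        n_communities=ncomm,
        modularity=q,
    )


_WORD_MEASURES = ("log10_frequency", "length", "degree", "clustering", "closeness")


@dataclass
class BackboneReport:
    """Paired network report plus retained/removed word-class comparison."""

    original: NetworkReportRow
    backbone: NetworkReportRow
    retained_words: list
    removed_words: list
    class_means: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    class_tests: dict[str, WelchResult] = field(default_factory=dict)


def backbone_comparison(
    original: nx.Graph,
    backbone: nx.Graph,
    seed: int = 0,
) -> BackboneReport:
    """Compare a network with its backbone, mirroring the standard report.

    Network-level rows are computed for both graphs. Word-level measures
    (degree, clustering, closeness from the *original* network; length and
    log10 frequency from node attributes) are compared between words of the
    original giant component that remain in the backbone giant component and
    those that drop out, with Welch t-tests per measure (retained minus
    removed).
    """
    if set(original.nodes) != set(backbone.nodes):
        raise ValueError("original and backbone must share the same node set")

    report = BackboneReport(
        original=_report_row(original, seed),
        backbone=_report_row(backbone, seed),
        retained_words=[],
        removed_words=[],
    )
    orig_gc = set(giant_component(original).nodes)
    try:
        bb_gc = set(giant_component(backbone).nodes)
    except ValueError:
        bb_gc = set()
    report.retained_words = sorted(orig_gc & bb_gc, key=str)
    report.removed_words = sorted(orig_gc - bb_gc, key=str)

    measures = word_measures(original, nodes=sorted(orig_gc, key=str))
    a = measures.loc[report.retained_words]
    b = measures.loc[report.removed_words]
    for col in _WORD_MEASURES:
        va = a[col].dropna().to_numpy()
        vb = b[col].dropna().to_numpy()
        report.class_means[col] = {
            "retained": (float(np.mean(va)) if len(va) else float("nan"),
                         float(np.std(va)) if len(va) else float("nan")),
            "removed": (float(np.mean(vb)) if len(vb) else float("nan"),
                        float(np.std(vb)) if len(vb) else float("nan")),
        }
        if len(va) >= 2 and len(vb) >= 2:
            try:
                report.class_tests[col] = compare_groups(va, vb)
            except ValueError:
                pass
    return report
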