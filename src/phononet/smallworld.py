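"""Small-world analysis against matched Erdős–Rényi ensembles.

A network is conventionally called small-world when its average shortest
path length L is comparable to that of an equivalent random graph while its
average clustering C is much higher. The Humphries–Gurney coefficient

    S = (C / C_ER) / (L / L_ER)

condenses this into a single number; S > 3 is the usual small-world
threshold. Following standard practice, L and C are computed on the giant
component and the random ensemble is G(n, m)-matched to the giant
component's node and edge counts, with ensemble means taken over a fixed
number of replicates (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .descriptives import aspl_and_diameter, giant_component

__all__ = ["SmallWorldResult", "ERSummary", "aspl_giant", "er_ensemble",
           "small_worldness_S", "small_world_analysis"]


@dataclass(frozen=True)
class SmallWorldResult:
    aspl: float
    cc: float
    aspl_er: float
    cc_er: float
    s: float
    reps: int
    seed: int

    def identity_holds(self) -> bool:
        return self.s == (self.cc / self.cc_er) / (self.aspl / self.aspl_er)


@dataclass(frozen=True)
class ERSummary:
    aspl_mean: float
    cc_mean: float
    aspl_values: tuple[float, ...]
    cc_values: tuple[float, ...]


def aspl_giant(network: nx.Graph) -> float:
    """Mean shortest-path length over unordered node pairs of the GC."""
    gc = giant_component(network)
    aspl, _ = aspl_and_diameter(gc)
    return aspl


def er_ensemble(
    n: int, m: int, reps: int = 10, seed: int = 0
) -> tuple[list[nx.Graph], ERSummary]:
    """Sample ``reps`` uniform G(n, m) graphs and summarize them.

    ASPL is computed on each replicate's largest component (sparse random
    graphs are typically disconnected); clustering is averaged over all n
    nodes. Deterministic given the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if m > n * (n - 1) // 2:
        raise ValueError(f"m={m} infeasible for n={n}")
    rng = np.random.default_rng(seed)
    graphs: list[nx.Graph] = []
    aspls, ccs = [], []
    for _ in range(reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        graphs.append(g)
        gc = giant_component(g)
        aspl, _ = aspl_and_diameter(gc)
        aspls.append(aspl)
        ccs.append(nx.average_clustering(g))
    summary = ERSummary(
        aspl_mean=float(np.mean(aspls)),
        cc_mean=float(np.mean(ccs)),
        aspl_values=tuple(aspls),
        cc_values=tuple(ccs),
    )
    return graphs, summary


def small_worldness_S(L: float, L_er: float, C: float, C_er: float) -> float:
    """Humphries–Gurney S = (C/C_ER) / (L/L_ER)."""
    for name, v in (("L", L), ("L_ER", L_er), ("C", C), ("C_ER", C_er)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (C / C_er) / (L / L_er)


def small_world_analysis(network: nx.Graph, reps: int = 10, seed: int = 0) -> SmallWorldResult:
    """Full small-world analysis of a network's giant component."""
    gc = giant_component(network)
    aspl, _ = aspl_and_diameter(gc)
    cc = float(nx.average_clustering(gc))
    _, er = er_ensemble(gc.number_of_nodes(), gc.number_of_edges(), reps=reps, seed=seed)
    s = small_worldness_S(aspl, er.aspl_mean, cc, er.cc_mean)
    return SmallWorldResult(
        aspl=aspl, cc=cc, aspl_er=er.aspl_mean, cc_er=er.cc_mean,
        s=s, reps=reps, seed=seed,
    )
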