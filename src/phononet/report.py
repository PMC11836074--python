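"""Report-table emission with fixed column orders and rounding.

Rounding conventions are fixed so that reruns diff cleanly: densities to
3 significant figures, percentages to 2 decimal places, means and other
reals to 2 decimals (4 for ASPL and modularity-like quantities where the
extra digits carry information).
"""

from __future__ import annotations

import math
from typing import Iterable

from .backbone import BackboneReport
from .descriptives import ComponentSummary, NetworkSummary
from .smallworld import SmallWorldResult

__all__ = [
    "sig3", "pct2", "mean2", "count_pct",
    "components_row", "summary_row", "smallworld_row", "fits_rows",
    "backbone_rows", "write_tsv",
]


def sig3(x: float) -> str:
    """3-significant-figure decimal rendering (for densities)."""
    if x == 0:
        return "0.00"
    exp = math.floor(math.log10(abs(x)))
    return f"{x:.{max(2 - exp, 0)}f}"


def pct2(x: float) -> str:
    return f"{x:.2f}"


def mean2(x: float) -> str:
    return f"{x:.2f}"


def count_pct(count: int, pct: float) -> str:
    return f"{count} ({pct2(pct)})"


COMPONENT_COLUMNS = [
    "nodes", "links", "density", "giant", "islands_nodes", "hermits", "islands",
]


def components_row(label: str, n: int, e: int, comps: ComponentSummary, dens: float) -> list[str]:
    """One Table-1-shaped row: counts with percentage parentheticals."""
    return [
        label,
        str(n),
        str(e),
        sig3(dens),
        count_pct(comps.giant_nodes, comps.giant_pct),
        count_pct(comps.island_nodes, comps.island_pct),
        count_pct(comps.hermit_nodes, comps.hermit_pct),
        str(comps.island_count),
    ]


SUMMARY_COLUMNS = [
    "nodes", "nodes_gc", "edges", "assortativity", "heterogeneity",
    "degree_mean", "degree_max", "degree_sd",
]


def summary_row(label: str, s: NetworkSummary, e_gc: int | None = None) -> list[str]:
    """One Table-5-shaped row (degree stats over the giant component)."""
    return [
        label,
        str(s.n),
        str(s.components.giant_nodes),
        str(e_gc if e_gc is not None else s.e),
        mean2(s.assortativity) if s.assortativity is not None else "NA",
        mean2(s.heterogeneity) if s.heterogeneity is not None else "NA",
        mean2(s.degree_mean),
        str(s.degree_max),
        mean2(s.degree_sd),
    ]


SMALLWORLD_COLUMNS = ["aspl", "aspl_er", "cc", "cc_er", "s"]


def smallworld_row(label: str, r: SmallWorldResult) -> list[str]:
    return [label, f"{r.aspl:.4f}", f"{r.aspl_er:.4f}", f"{r.cc:.4f}",
            f"{r.cc_er:.4f}", mean2(r.s)]


FIT_COLUMNS = ["family", "ks_distance", "params"]


def fits_rows(label: str, fits) -> list[list[str]]:
    rows = []
    for f in fits:
        params = " ".join(f"{k}={v:.4f}" for k, v in f.params.items())
        rows.append([label, f.family, f"{f.ks_distance:.4f}", params])
    return rows


BACKBONE_ROW_LABELS = [
    "nodes", "edges", "gc_nodes", "gc_edges", "degree_mean", "degree_mean_gc",
    "diameter_gc", "aspl_gc", "components", "component_size_range",
    "isolates", "avg_clustering", "communities",
]


def backbone_rows(report: BackboneReport) -> list[list[str]]:
    """Table-2-shaped paired rows: measure, original value, backbone value."""
    def col(r):
        return [
            str(r.n),
            str(r.e),
            count_pct(r.gc_nodes, r.gc_nodes_pct),
            count_pct(r.gc_edges, r.gc_edges_pct),
            mean2(r.degree_mean),
            mean2(r.degree_mean_gc),
            str(r.diameter_gc),
            f"{r.aspl_gc:.4f}",
            str(r.island_count),
            f"{r.component_size_min}-{r.component_size_max}",
            count_pct(r.isolates, r.isolates_pct),
            mean2(r.avg_clustering),
            f"{r.n_communities} (Q = {r.modularity:.2f})",
        ]
    orig, bb = col(report.original), col(report.backbone)
    return [
        [label, o, b] for label, o, b in zip(BACKBONE_ROW_LABELS, orig, bb)
    ]


def write_tsv(path, header: Iterable[str], rows: Iterable[Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
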