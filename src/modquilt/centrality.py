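"""Module graph construction, degree/betweenness centrality, hub calling.

The module is binarized into an undirected, unweighted graph by
thresholding the soft-powered adjacency; hub genes are nodes with degree
>= 250 and raw (unnormalized) betweenness >= 2,500, both inclusive.
Betweenness counts each unordered pair once and excludes endpoints
(Brandes' algorithm via networkx).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .coexpr import Network

__all__ = ["ModuleGraph", "build_graph", "degree", "betweenness", "centrality_table", "select_hubs"]


@dataclass
class ModuleGraph:
    graph: nx.Graph
    edge_threshold: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


def build_graph(network: Network, member_probes, edge_threshold: float = 0.1) -> ModuleGraph:
    """Edge (i, j) iff a_ij >= edge_threshold, i != j."""
    if not (0 < edge_threshold <= 1):
        raise ValueError("edge_threshold must be in (0, 1]")
    members = list(member_probes)
    pos = {p: network.probe_ids.index(p) for p in members}
    g = nx.Graph()
    g.add_nodes_from(members)
    a = network.adjacency
    for i, pi in enumerate(members):
        for pj in members[i + 1 :]:
            if a[pos[pi], pos[pj]] >= edge_threshold:
                g.add_edge(pi, pj)
    return ModuleGraph(g, edge_threshold)


def degree(module_graph: ModuleGraph) -> pd.Series:
    g = module_graph.graph
    return pd.Series({n: d for n, d in g.degree()}, name="degree").astype(int)


def betweenness(module_graph: ModuleGraph) -> pd.Series:
    """Raw betweenness: unordered pairs counted once, endpoints excluded."""
    vals = nx.betweenness_centrality(module_graph.graph, normalized=False)
    return pd.Series(vals, name="betweenness", dtype=float)


def centrality_table(module_graph: ModuleGraph, degree_min: float = 250, betweenness_min: float = 2500) -> pd.DataFrame:
    deg = degree(module_graph)
    btw = betweenness(module_graph)
    tab = pd.DataFrame({"degree": deg, "betweenness": btw})
    tab["hub"] = (tab["degree"] >= degree_min) & (tab["betweenness"] >= betweenness_min)
    return tab


def select_hubs(table: pd.DataFrame, degree_min: float = 250, betweenness_min: float = 2500) -> list:
    """Hubs are nodes passing both inclusive cutoffs (conjunction)."""
    if degree_min < 0 or betweenness_min < 0:
        raise ValueError("thresholds must be >= 0")
    mask = (table["degree"] >= degree_min) & (table["betweenness"] >= betweenness_min)
    return list(table.index[mask])
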