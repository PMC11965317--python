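"""Reaction-adjacency graph and metabolite-degree-weighted distances.

Two directed reactions are adjacent when a metabolite produced by one is
consumed by the other.  The naive distance between a reaction pair is the
number of reactions between them plus one (each hop costs 1).  The weighted
metabolic distance up-scales a hop through a highly connected (hub)
metabolite: a bridging metabolite of degree ``deg`` costs

    w(m) = max(1, 1 + log2(deg / 2))

so a degree-2 metabolite — a strictly linear link — costs exactly 1 and the
weighted distance reduces to the naive one along linear pathways, while
hops through hubs like pyruvate or ATP become long and effectively decouple
cross-pathway reactions.  When several metabolites bridge the same pair,
the cheapest bridge defines the hop cost.

Distances from a reaction of interest (ROI) are direction-aware: a path
must follow mass flow, either from the ROI downstream to a reaction or from
a reaction downstream into the ROI.  The neighborhood distance of the ROI
to a reaction is the shorter of the two.  Reactions connected to the ROI
only by mixed-direction routes (e.g. two reactions that both feed a common
consumer) are unreachable and take distance +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .model_io import DirectedNetwork

__all__ = [
    "metabolite_degree",
    "metabolite_weight",
    "edge_length",
    "build_reaction_graph",
    "shortest_distances",
    "distance_row",
    "DistanceMap",
    "compute_distance_map",
    "effective_boundary",
]


def metabolite_degree(dnet: DirectedNetwork, met: str) -> int:
    """Number of distinct base reactions producing plus consuming ``met``.

    A reversible base reaction counts once per role (it both produces and
    consumes), not once per direction.
    """
    if met not in {m.id for m in dnet.metabolites}:
        raise KeyError(f"unknown metabolite {met!r}")
    producers = {r.base_id for r in dnet.producers(met)}
    consumers = {r.base_id for r in dnet.consumers(met)}
    return len(producers) + len(consumers)


def metabolite_weight(degree: int) -> float:
    """Hop cost through a metabolite of the given degree; >= 1 always."""
    if degree <= 0:
        return 1.0
    return max(1.0, 1.0 + math.log2(degree / 2.0))


def edge_length(bridge_degrees) -> float:
    """Cost of a hop given the degrees of all bridging metabolites.

    The cheapest bridge defines adjacency: one strictly linear carrier is
    enough for flux coupling regardless of how connected the others are.
    """
    degrees = list(bridge_degrees)
    if not degrees:
        raise ValueError("at least one bridging metabolite required")
    return min(metabolite_weight(d) for d in degrees)


def build_reaction_graph(dnet: DirectedNetwork) -> nx.DiGraph:
    """Directed reaction-adjacency graph with naive and weighted hop costs.

    Nodes are directed reaction ids.  An edge u -> v exists when u produces
    a metabolite that v consumes; the two directions of one base reaction
    are never linked (a reaction is not its own neighbor).
    """
    g = nx.DiGraph()
    g.add_nodes_from(r.id for r in dnet.reactions)
    deg_cache = {m.id: metabolite_degree(dnet, m.id) for m in dnet.metabolites}
    for m in dnet.metabolites:
        prods = dnet.producers(m.id)
        cons = dnet.consumers(m.id)
        if not prods or not cons:
            continue
        w = metabolite_weight(deg_cache[m.id])
        for u in prods:
            for v in cons:
                if u.id == v.id or u.base_id == v.base_id:
                    continue
                if g.has_edge(u.id, v.id):
                    data = g[u.id][v.id]
                    data["bridges"].append(m.id)
                    data["weighted"] = min(data["weighted"], w)
                else:
                    g.add_edge(u.id, v.id, bridges=[m.id], weighted=w, naive=1.0)
    return g


def shortest_distances(
    graph: nx.DiGraph, roi: str, metric: str = "weighted"
) -> dict[str, float]:
    """Single-source Dijkstra distances along mass flow; unreachable -> +inf."""
    if roi not in graph:
        raise KeyError(f"ROI {roi!r} not in graph")
    if metric not in ("naive", "weighted"):
        raise ValueError(f"unknown metric {metric!r}")
    dist = nx.single_source_dijkstra_path_length(graph, roi, weight=metric)
    return {n: dist.get(n, math.inf) for n in graph.nodes}


def distance_row(
    graph: nx.DiGraph, roi: str, metric: str = "weighted"
) -> dict[str, float]:
    """Neighborhood distance from the ROI to every directed reaction.

    min(downstream distance ROI -> r, upstream distance r -> ROI); both legs
    follow mass flow, so parallel branches that merely share a downstream
    consumer remain at +inf.
    """
    down = shortest_distances(graph, roi, metric)
    up = shortest_distances(graph.reverse(copy=False), roi, metric)
    return {n: min(down[n], up[n]) for n in graph.nodes}


@dataclass
class DistanceMap:
    """Naive and weighted neighborhood distances from one ROI direction."""

    roi: str
    naive: dict[str, float]
    weighted: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"naive_d": pd.Series(self.naive),
             "weighted_d": pd.Series(self.weighted)}
        ).rename_axis("reaction_id")


def compute_distance_map(graph: nx.DiGraph, roi: str) -> DistanceMap:
    return DistanceMap(
        roi=roi,
        naive=distance_row(graph, roi, "naive"),
        weighted=distance_row(graph, roi, "weighted"),
    )


def effective_boundary(distmap: DistanceMap, b: float) -> float:
    """Interpretable pathway length reached by a weighted boundary ``b``:
    the maximum naive distance among reactions within weighted distance b.
    Returns 0 when nothing but the ROI lies within the boundary.
    """
    best = 0.0
    for rid, wd in distmap.weighted.items():
        if wd <= b and math.isfinite(wd):
            nd = distmap.naive[rid]
            if math.isfinite(nd):
                best = max(best, nd)
    return best


def write_distance_tsv(maps: list[DistanceMap], path) -> None:
    rows = []
    for dm in maps:
        for rid in dm.naive:
            rows.append(
                {"roi_id": dm.roi, "reaction_id": rid,
                 "naive_d": dm.naive[rid], "weighted_d": dm.weighted[rid]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
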