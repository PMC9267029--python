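"""Binding network: PM nodes, COM-distance edges, hubs, backbone, pathway.

Binding modes become nodes of an undirected graph; two modes are candidate
neighbours when the distance d_PM between their centers of mass is within the
edge cutoff (12 Å by default — roughly one ligand length, so an edge is a
single-step ligand move).  Each node retains at most ``max_edges`` of its
nearest candidates; a surviving edge is one kept by either endpoint, and any
node still over the cap afterwards has its longest edges pruned (longest
first, deterministic tie-breaks).  Modes left without any edge are excluded
from the graph.  Nodes with more than ``hub_threshold`` edges are hubs; the
backbone is the largest connected component of the hub-induced subgraph —
the ligand's main binding highway.  A representative pathway is the
minimum-total-length route from the outermost node (largest d_D) to the node
nearest the destination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, squareform

from .clustering import BindingMode

__all__ = [
    "BindingNetwork",
    "pm_distance_matrix",
    "destination_mode",
    "build_network",
    "extract_backbone",
    "suggest_pathway",
]

EDGE_CUTOFF = 12.0   # Å, inclusive
MAX_EDGES = 10       # per-node degree cap
HUB_THRESHOLD = 4    # hub iff degree > 4


def pm_distance_matrix(pms: Sequence[BindingMode]) -> np.ndarray:
    """Symmetric matrix of COM distances d_PM (Å), zero diagonal."""
    if not pms:
        raise ValueError("need at least one binding mode")
    coms = np.asarray([m.com for m in pms], dtype=float)
    return cdist(coms, coms)


@dataclass
class BindingNetwork:
    """Graph over binding modes, with hub/backbone classification.

    ``graph`` holds only connected PMs (nodes keyed by pm_id, with ``d_D``,
    ``e_inter``, ``degree``, ``is_hub`` and ``in_backbone`` attributes; edges
    weighted by d_PM in Å).  ``excluded_ids`` lists PMs dropped for having no
    neighbour within the cutoff.
    """

    graph: nx.Graph
    hub_ids: list[int]
    backbone: nx.Graph
    excluded_ids: list[int]
    edge_cutoff: float
    max_edges: int | None
    hub_threshold: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, pm_id: int) -> int:
        return self.graph.degree[pm_id]

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"pm_id": n, **self.graph.nodes[n], "degree": self.graph.degree[n]}
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"pm_a": min(a, b), "pm_b": max(a, b),
             "d_PM_A": self.graph.edges[a, b]["weight"]}
            for a, b in self.graph.edges
        ]
        return pd.DataFrame(rows).sort_values(["pm_a", "pm_b"]).reset_index(drop=True) \
            if rows else pd.DataFrame(columns=["pm_a", "pm_b", "d_PM_A"])

    def write_edge_list(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_node_table(self, path: str | Path) -> None:
        self.node_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def _cap_degrees(g: nx.Graph, max_edges: int) -> None:
    # union rule first: an edge survives if either endpoint ranks it among
    # its max_edges nearest.  Prune leftover over-cap nodes longest-edge-first.
    keep: set[tuple[int, int]] = set()
    for n in g.nodes:
        nbrs = sorted(g[n], key=lambda m: (g.edges[n, m]["weight"], m))
        for m in nbrs[:max_edges]:
            keep.add((min(n, m), max(n, m)))
    drop = [e for e in g.edges if (min(e), max(e)) not in keep]
    g.remove_edges_from(drop)
    while True:
        over = [n for n in g.nodes if g.degree[n] > max_edges]
        if not over:
            break
        n = min(over, key=lambda v: (-g.degree[v], v))
        m = max(g[n], key=lambda v: (g.edges[n, v]["weight"], v))
        g.remove_edge(n, m)


def destination_mode(destination, e_inter: float = float("nan")) -> BindingMode:
    """The destination pose as a pseudo-mode (pm_id 0, d_D = 0) so it can be
    appended to the PM list when the network should contain the destination
    as an explicit node."""
    from .structures import Structure

    com = (destination.center_of_mass()
           if isinstance(destination, Structure) else np.asarray(destination, float))
    return BindingMode(pm_id=0, representative=-1, e_inter=e_inter,
                       d_D=0.0, com=com, members=[])


def build_network(pms: Sequence[BindingMode],
                  edge_cutoff: float = EDGE_CUTOFF,
                  max_edges: int | None = MAX_EDGES,
                  hub_threshold: int = HUB_THRESHOLD) -> BindingNetwork:
    """Build the binding network over ``pms``.

    Candidate edges connect PM pairs with d_PM ≤ ``edge_cutoff`` (inclusive).
    ``max_edges=None`` lifts the degree cap, giving the pure cutoff graph.
    To count the destination pose as a node, append :func:`destination_mode`
    to ``pms``.
    """
    if edge_cutoff <= 0:
        raise ValueError("edge cutoff must be positive")
    if not pms:
        raise ValueError("need at least one binding mode")
    ids = [m.pm_id for m in pms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pm_id values")

    d = pm_distance_matrix(pms)
    g = nx.Graph()
    g.add_nodes_from(
        (m.pm_id, {"d_D": float(m.d_D), "e_inter": float(m.e_inter)})
        for m in pms
    )
    k = len(pms)
    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] <= edge_cutoff:
                g.add_edge(ids[i], ids[j], weight=float(d[i, j]))

    if max_edges is not None:
        _cap_degrees(g, max_edges)

    excluded = sorted(n for n in g.nodes if g.degree[n] == 0)
    g.remove_nodes_from(excluded)

    hubs = sorted(n for n in g.nodes if g.degree[n] > hub_threshold)
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
        g.nodes[n]["is_hub"] = n in hubs

    net = BindingNetwork(graph=g, hub_ids=hubs, backbone=nx.Graph(),
                         excluded_ids=excluded, edge_cutoff=edge_cutoff,
                         max_edges=max_edges, hub_threshold=hub_threshold)
    net.backbone = extract_backbone(net)
    bb = set(net.backbone.nodes)
    for n in g.nodes:
        g.nodes[n]["in_backbone"] = n in bb
    return net


def extract_backbone(net: BindingNetwork) -> nx.Graph:
    """Largest connected component of the hub-induced subgraph (ties broken
    by the component containing the lowest pm_id)."""
    sub = net.graph.subgraph(net.hub_ids)
    comps = list(nx.connected_components(sub))
    if not comps:
        return nx.Graph()
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return nx.Graph(sub.subgraph(best))


def suggest_pathway(net: BindingNetwork,
                    source: int | None = None,
                    sink: int | None = None) -> pd.DataFrame:
    """Minimum-total-d_PM path from ``source`` (default: node with maximal
    d_D) to ``sink`` (default: node with minimal d_D).

    Returns a table of path nodes in order, flagging hubs and backbone
    members.  Raises ``nx.NetworkXNoPath`` if the endpoints are disconnected.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if source is None:
        source = max(g.nodes, key=lambda n: (g.nodes[n]["d_D"], -n))
    if sink is None:
        sink = min(g.nodes, key=lambda n: (g.nodes[n]["d_D"], n))
    for label, node in (("source", source), ("sink", sink)):
        if node not in g:
            raise ValueError(f"{label} node {node} not in network")
    path = nx.dijkstra_path(g, source, sink, weight="weight")
    rows = []
    for i, n in enumerate(path):
        rows.append({
            "step": i,
            "pm_id": n,
            "d_D_A": g.nodes[n]["d_D"],
            "is_hub": g.nodes[n]["is_hub"],
            "in_backbone": g.nodes[n]["in_backbone"],
            "edge_to_next_A": (g.edges[n, path[i + 1]]["weight"]
                               if i + 1 < len(path) else np.nan),
        })
    return pd.DataFrame(rows)
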