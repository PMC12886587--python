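"""Thresholded correlation graphs and k-nearest-neighbour edge reduction.

Graphs are plain :class:`networkx.Graph` objects.  Nodes are entity ids with
a ``group`` attribute; edges carry ``weight`` equal to the correlation
coefficient; construction parameters are stored under ``G.graph["provenance"]``
so an exported file records how it was built.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .correlation import CorrelationResult

__all__ = [
    "build_network",
    "knn_reduce",
    "connected_components",
    "group_mixing",
    "GroupMixing",
    "export_graph",
    "import_graph",
]


def build_network(
    corr: CorrelationResult,
    r_min: float,
    alpha: float,
    node_groups: Mapping | None = None,
) -> nx.Graph:
    """Keep edge (i, j) iff r_ij > r_min (strict) and p_ij < alpha.

    Every entity becomes a node even if isolated, so components and mixing
    statistics see the full cohort.
    """
    if not -1.0 <= r_min <= 1.0:
        raise ValueError("r_min must lie in [-1, 1]")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    g = nx.Graph()
    g.graph["provenance"] = {
        "r_min": r_min,
        "alpha": alpha,
        "k": None,
        "method": corr.method,
        "m": corr.m,
    }
    ids = corr.entity_ids
    for e in ids:
        attrs = {}
        if node_groups is not None:
            attrs["group"] = node_groups[e]
        g.add_node(e, **attrs)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr.r_matrix[i, j]
            if r > r_min and corr.p_matrix[i, j] < alpha:
                g.add_edge(ids[i], ids[j], weight=float(r))
    return g


def knn_reduce(g: nx.Graph, k: int, semantics: str = "union") -> nx.Graph:
    """Retain only each node's k strongest-weighted edges, keeping ties.

    With ``union`` semantics (default) an edge survives if it ranks within the
    top k — including everything tied with the k-th weight — for *either*
    endpoint, so a node never loses its own strongest edges.  ``intersection``
    requires the rank for both endpoints.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if semantics not in ("union", "intersection"):
        raise ValueError(f"unknown semantics {semantics!r}")
    cutoff = {}
    for u in g.nodes:
        weights = sorted((d["weight"] for _, _, d in g.edges(u, data=True)), reverse=True)
        cutoff[u] = weights[min(k, len(weights)) - 1] if weights else None

    def keeps(u, w):
        return cutoff[u] is not None and w >= cutoff[u]

    out = nx.Graph()
    out.graph.update(g.graph)
    prov = dict(out.graph.get("provenance", {}))
    prov["k"] = k
    out.graph["provenance"] = prov
    out.add_nodes_from(g.nodes(data=True))
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        ok = keeps(u, w) or keeps(v, w) if semantics == "union" else keeps(u, w) and keeps(v, w)
        if ok:
            out.add_edge(u, v, **d)
    return out


def connected_components(g: nx.Graph) -> list:
    """Maximal connected node sets, largest first."""
    return sorted(nx.connected_components(g), key=len, reverse=True)


@dataclass(frozen=True)
class GroupMixing:
    """Between-group edge fraction plus within-group edge densities."""

    between_fraction: float
    within_density: dict
    n_edges: int


def group_mixing(g: nx.Graph, groups: Mapping | None = None) -> GroupMixing:
    """How much the graph's edges mix the two experimental groups."""
    if groups is None:
        groups = {n: d.get("group") for n, d in g.nodes(data=True)}
    missing = [n for n in g.nodes if groups.get(n) is None]
    if missing:
        raise ValueError(f"nodes lack a group attribute: {missing}")
    edges = list(g.edges)
    between = sum(groups[u] != groups[v] for u, v in edges)
    frac = between / len(edges) if edges else float("nan")
    density = {}
    for grp in sorted(set(groups.values())):
        members = [n for n in g.nodes if groups[n] == grp]
        possible = len(members) * (len(members) - 1) / 2
        present = sum(
            groups[u] == grp and groups[v] == grp for u, v in edges
        )
        density[grp] = present / possible if possible else float("nan")
    return GroupMixing(between_fraction=frac, within_density=density, n_edges=len(edges))


def _flatten_provenance(g: nx.Graph) -> nx.Graph:
    # GraphML stores scalar attributes only; dicts are flattened to keys.
    out = g.copy()
    prov = out.graph.pop("provenance", None)
    if prov:
        for key, val in prov.items():
            if val is not None:
                out.graph[f"provenance_{key}"] = val
    return out


def export_graph(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the graph losslessly as GraphML or an edge-list CSV.

    Both formats load into Graphia; GraphML keeps node group attributes and
    provenance, the CSV keeps source, target, weight columns.  Weights are
    serialised at full double precision.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_flatten_provenance(g), path)
    elif fmt == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source,target,weight\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u},{v},{d['weight']!r}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Inverse of :func:`export_graph` (provenance stays flattened)."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edgelist":
        g = nx.Graph()
        with path.open(encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "source,target,weight":
                raise ValueError(f"{path}: not an edge-list CSV")
            for line in fh:
                u, v, w = line.rstrip("\n").split(",")
                g.add_edge(u, v, weight=float(w))
        return g
    raise ValueError(f"unknown format {fmt!r}")
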