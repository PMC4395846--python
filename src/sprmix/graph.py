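"""SPR tree-space graphs over the top trees of a posterior sample.

Nodes are the top trees (95% credible set capped at m = 4096), annotated
with posterior probability and SPR distance from the MAP tree; edges join
pairs at SPR distance exactly 1.  Topological peaks show up as large
disconnected components or as high-probability regions joined only through
low-probability trees.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx

from .trees import PosteriorSummary, Topology, top_trees
from .spr import cached_spr_distance, spr_neighborhood

__all__ = [
    "SprGraph",
    "build_spr_graph",
    "connected_components",
    "export_graph",
    "import_graph",
    "export_weighted_graph",
]

OTHER = "__other__"


@dataclass
class SprGraph:
    """An SPR graph: ``graph`` is a networkx Graph whose nodes are
    :class:`Topology` objects carrying ``index``, ``probability``,
    ``distance_from_map`` and ``cluster`` attributes."""

    graph: nx.Graph
    map_tree: Topology

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes, key=lambda t: self.graph.nodes[t]["index"])

    def probability(self, t: Topology) -> float:
        return self.graph.nodes[t]["probability"]

    @property
    def total_probability(self) -> float:
        return sum(d["probability"] for _, d in self.graph.nodes(data=True))

    def set_clusters(self, assignment: dict) -> None:
        for t in self.graph.nodes:
            self.graph.nodes[t]["cluster"] = assignment.get(t, -1)


def build_spr_graph(
    summary: PosteriorSummary,
    m: int = 4096,
    level: float = 0.95,
    distance_mode: str = "leaf",
) -> SprGraph:
    """Build the SPR graph of the top trees.

    Edges are found by neighborhood hashing (each node's SPR neighborhood
    enumerated once, looked up in canonical form), which is exact for the
    distance-1 relation.  Each node's SPR distance to the MAP tree is
    computed with the best-rooting distance; ``distance_mode="leaf"``
    (default) pairs rootings at a shared leaf, ``"all"`` minimizes over all
    rooting pairs.
    """
    tops = top_trees(summary, m=m, level=level)
    if not tops:
        raise ValueError("empty summary")
    g = nx.Graph()
    index = {t: i for i, t in enumerate(tops)}
    map_tree = tops[0]
    for i, t in enumerate(tops):
        g.add_node(
            t,
            index=i,
            probability=summary.frequency(t),
            distance_from_map=(
                0 if t == map_tree else cached_spr_distance(map_tree, t, mode=distance_mode)
            ),
            cluster=-1,
        )
    topset = set(tops)
    for t in tops:
        for u in spr_neighborhood(t):
            if u in topset and index[u] > index[t]:
                g.add_edge(t, u)
    return SprGraph(graph=g, map_tree=map_tree)


def connected_components(spr_graph: SprGraph) -> list:
    """Graph components with their cumulative posterior probability,
    ordered by descending probability mass."""
    comps = []
    for comp in nx.connected_components(spr_graph.graph):
        mass = sum(spr_graph.probability(t) for t in comp)
        comps.append((set(comp), mass))
    comps.sort(key=lambda c: (-c[1], min(t.newick for t in c[0])))
    return comps


_NODE_COLS = ["index", "topology", "probability", "distance_from_map", "cluster"]


def export_graph(spr_graph: SprGraph, basepath, format: str = "edge-list") -> list:
    """Write the graph for visualization (Cytoscape-compatible).

    ``edge-list`` writes ``<basepath>.nodes.tsv`` (node attribute table)
    and ``<basepath>.edges.tsv`` (source/target indices); ``graphml``
    writes ``<basepath>.graphml`` with the same attributes.  Output is
    deterministic, so export -> import -> export round-trips byte-wise.
    """
    basepath = os.fspath(basepath)
    if format == "edge-list":
        nodes_path = basepath + ".nodes.tsv"
        edges_path = basepath + ".edges.tsv"
        g = spr_graph.graph
        with open(nodes_path, "w") as fh:
            fh.write("\t".join(_NODE_COLS) + "\n")
            for t in spr_graph.nodes:
                d = g.nodes[t]
                fh.write(
                    f"{d['index']}\t{t.newick}\t{d['probability']!r}\t"
                    f"{d['distance_from_map']}\t{d['cluster']}\n"
                )
        idx = {t: g.nodes[t]["index"] for t in g.nodes}
        rows = sorted(
            (min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in g.edges
        )
        with open(edges_path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in rows:
                fh.write(f"{a}\t{b}\n")
        return [nodes_path, edges_path]
    if format == "graphml":
        path = basepath + ".graphml"
        h = nx.Graph()
        for t in spr_graph.nodes:
            d = spr_graph.graph.nodes[t]
            h.add_node(t.newick, **{k: d[k] for k in ("index", "probability", "distance_from_map", "cluster")})
        for a, b in spr_graph.graph.edges:
            h.add_edge(a.newick, b.newick)
        nx.write_graphml(h, path)
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def import_graph(basepath) -> SprGraph:
    """Rebuild an :class:`SprGraph` from an edge-list export."""
    basepath = os.fspath(basepath)
    g = nx.Graph()
    by_index: dict[int, Topology] = {}
    with open(basepath + ".nodes.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == _NODE_COLS
        for line in fh:
            idx_s, newick, prob_s, dist_s, cluster_s = line.rstrip("\n").split("\t")
            t = Topology.from_newick(newick)
            by_index[int(idx_s)] = t
            g.add_node(
                t,
                index=int(idx_s),
                probability=float(prob_s),
                distance_from_map=None if dist_s == "None" else int(dist_s),
                cluster=int(cluster_s),
            )
    with open(basepath + ".edges.tsv") as fh:
        fh.readline()
        for line in fh:
            a, b = line.split()
            g.add_edge(by_index[int(a)], by_index[int(b)])
    map_tree = max(g.nodes, key=lambda t: (g.nodes[t]["probability"], -g.nodes[t]["index"]))
    return SprGraph(graph=g, map_tree=map_tree)


def export_weighted_graph(graph: nx.Graph, basepath) -> list:
    """Edge-list export for weighted MCMC transition graphs (nodes are
    topologies or the "other" sink; edges carry transition counts, nodes
    carry dwell counts)."""
    basepath = os.fspath(basepath)
    nodes_path = basepath + ".nodes.tsv"
    edges_path = basepath + ".edges.tsv"
    names = {}
    for n in graph.nodes:
        names[n] = n.newick if isinstance(n, Topology) else str(n)
    order = sorted(graph.nodes, key=lambda n: (graph.nodes[n].get("index", 1 << 30), names[n]))
    idx = {n: i for i, n in enumerate(order)}
    with open(nodes_path, "w") as fh:
        fh.write("index\ttopology\tdwell\n")
        for n in order:
            fh.write(f"{idx[n]}\t{names[n]}\t{graph.nodes[n].get('dwell', 0)}\n")
    rows = sorted(
        (min(idx[a], idx[b]), max(idx[a], idx[b]), d["weight"])
        for a, b, d in graph.edges(data=True)
    )
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w}\n")
    return [nodes_path, edges_path]
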