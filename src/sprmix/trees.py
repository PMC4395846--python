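"""Topology containers and posterior-sample ingestion.

A *topology* here is an unrooted, binary, leaf-labeled tree shape: branch
lengths and support values are discarded on ingestion because the analyses
in this package act on the discrete topology space that phylogenetic MCMC
moves traverse.  Every topology is stored in a canonical form (rooted for
serialization at the internal vertex adjacent to the lexicographically
smallest leaf, children ordered by smallest contained leaf) so that two
inputs describing the same unrooted shape compare, hash, and serialize
identically regardless of rotation, reflection, or edge order.
"""

from __future__ import annotations

import math
import os
import random
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

import dendropy

__all__ = [
    "Topology",
    "ChainTrace",
    "PosteriorSummary",
    "MultifurcationError",
    "TaxonSetMismatchError",
    "parse_trees",
    "summarize",
    "top_trees",
    "resolution_count",
    "nontrivial_splits",
    "write_summary_tsv",
]


class MultifurcationError(ValueError):
    """Raised for input trees that are not fully resolved (binary)."""


class TaxonSetMismatchError(ValueError):
    """Raised when trees in one analysis do not share a single leaf set."""


# ---------------------------------------------------------------------------
# canonical shape machinery
#
# Shapes are nested tuples: a leaf is its label (str); an internal node is a
# 2-tuple of child shapes; the serialization root is a 3-tuple whose first
# element is the globally smallest leaf label.  Children are always ordered
# by their smallest contained leaf, which gives a total order on shapes.


def _shape_min(shape) -> str:
    # children are min-ordered, so the first path is the min path
    while not isinstance(shape, str):
        shape = shape[0]
    return shape


def _build_canonical(adj: dict, labels: dict, node: int, parent: int):
    if node in labels:
        return labels[node], labels[node]
    pairs = sorted(
        (_build_canonical(adj, labels, w, node) for w in adj[node] if w != parent),
        key=lambda p: p[0],
    )
    return pairs[0][0], tuple(p[1] for p in pairs)


def canonical_shape_from_adjacency(adj: dict, labels: dict):
    """Canonical 3-tuple shape for an unrooted binary tree given as an
    adjacency dict (node id -> set of node ids) plus a leaf label map."""
    min_node = min(labels, key=lambda n: labels[n])
    (v,) = adj[min_node]
    sides = sorted(
        (_build_canonical(adj, labels, w, v) for w in adj[v] if w != min_node),
        key=lambda p: p[0],
    )
    return (labels[min_node], sides[0][1], sides[1][1])


def _serialize(shape) -> str:
    if isinstance(shape, str):
        return shape
    return "(" + ",".join(_serialize(s) for s in shape) + ")"


def adjacency_from_shape(shape):
    """Inverse of canonicalization: adjacency dict plus leaf-label map.

    Node ids are ints; leaves carry entries in the returned ``labels`` map.
    """
    adj: dict[int, set[int]] = defaultdict(set)
    labels: dict[int, str] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0]

    def build(sub, parent: int) -> None:
        if isinstance(sub, str):
            nid = new_node()
            labels[nid] = sub
            adj[parent].add(nid)
            adj[nid].add(parent)
        else:
            nid = new_node()
            adj[parent].add(nid)
            adj[nid].add(parent)
            for child in sub:
                build(child, nid)

    root = 0
    adj[root] = set()
    first, s1, s2 = shape
    build(first, root)
    build(s1, root)
    build(s2, root)
    return dict(adj), labels


@dataclass(frozen=True)
class Topology:
    """An unrooted binary leaf-labeled tree topology in canonical form."""

    shape: tuple
    newick: str
    leaves: frozenset

    @classmethod
    def from_shape(cls, shape) -> "Topology":
        leaves = frozenset(_iter_leaves(shape))
        return cls(shape=shape, newick=_serialize(shape) + ";", leaves=leaves)

    @classmethod
    def from_adjacency(cls, adj: dict, labels: dict) -> "Topology":
        return cls.from_shape(canonical_shape_from_adjacency(adj, labels))

    @classmethod
    def from_newick(cls, text: str) -> "Topology":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return _topology_from_dendropy(tree)

    def adjacency(self):
        return adjacency_from_shape(self.shape)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.newick == other.newick

    def __hash__(self) -> int:
        return hash(self.newick)

    def __lt__(self, other: "Topology") -> bool:
        return self.newick < other.newick

    def __repr__(self) -> str:
        return f"Topology({self.newick!r})"


def _iter_leaves(shape):
    if isinstance(shape, str):
        yield shape
    else:
        for sub in shape:
            yield from _iter_leaves(sub)


def _topology_from_dendropy(tree: dendropy.Tree) -> Topology:
    adj: dict[int, set[int]] = defaultdict(set)
    labels: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj[id(node)].add(id(child))
            adj[id(child)].add(id(node))
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise ValueError("leaf without a label in input tree")
            labels[id(node)] = str(label)
    if len(set(labels.values())) != len(labels):
        raise ValueError("duplicate leaf labels in input tree")
    # suppress any degree-2 vertices (e.g. a rooted newick's seed node)
    for nid in [n for n in list(adj) if n not in labels and len(adj[n]) == 2]:
        a, b = adj.pop(nid)
        adj[a].discard(nid)
        adj[b].discard(nid)
        adj[a].add(b)
        adj[b].add(a)
    if len(labels) < 4:
        raise ValueError("topologies need at least 4 leaves")
    for nid, nbrs in adj.items():
        if nid in labels:
            if len(nbrs) != 1:
                raise MultifurcationError("leaf of degree != 1")
        elif len(nbrs) != 3:
            raise MultifurcationError(
                "multifurcating (or unresolved) input tree rejected; "
                "resolve polytomies before analysis"
            )
    return Topology.from_adjacency(adj, labels)


def shuffled_newick(topology: Topology, rng: random.Random) -> str:
    """An equivalent newick string with random rooting, child order and
    branch lengths.  Used to exercise canonicalization invariance."""
    adj, labels = topology.adjacency()
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    u, v = rng.choice(edges)

    def ser(node, parent) -> str:
        if node in labels:
            return f"{labels[node]}:{rng.random():.4f}"
        kids = [w for w in adj[node] if w != parent]
        rng.shuffle(kids)
        inner = ",".join(ser(w, node) for w in kids)
        return f"({inner}):{rng.random():.4f}"

    return f"({ser(u, v)},{ser(v, u)});"


# ---------------------------------------------------------------------------
# splits


def nontrivial_splits(topology: Topology) -> frozenset:
    """The n-3 nontrivial bipartitions of the leaf set, each represented
    side-invariantly by the block containing the smallest leaf label."""
    anchor = min(topology.leaves)
    out = []

    def collect(shape):
        # returns the leaf set below this node
        if isinstance(shape, str):
            return frozenset((shape,))
        below = frozenset().union(*(collect(s) for s in shape))
        if 1 < len(below) < len(topology.leaves) - 1:
            side = below if anchor in below else topology.leaves - below
            out.append(side)
        return below

    _, s1, s2 = topology.shape
    collect(s1)
    collect(s2)
    return frozenset(out)


# ---------------------------------------------------------------------------
# traces and summaries


@dataclass
class ChainTrace:
    """The ordered, subsampled topology sequence of one MCMC run."""

    run_id: str
    topologies: list
    interval: int = 1
    burnin_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.topologies)

    def __iter__(self):
        return iter(self.topologies)

    def __getitem__(self, i):
        return self.topologies[i]

    @property
    def leaves(self) -> frozenset:
        return self.topologies[0].leaves


def parse_trees(
    source,
    format: str = "newick",
    burnin_fraction: float = 0.25,
    interval: int = 1,
    run_id: str | None = None,
) -> ChainTrace:
    """Read a tree file (plain newick, one tree per line, or a Nexus trees
    block in the MrBayes .t dialect with TRANSLATE) into a :class:`ChainTrace`.

    The first ``burnin_fraction`` of samples is discarded.  Branch lengths,
    support values and comments are stripped; multifurcating trees are
    rejected; all trees must share one leaf-label set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown format {format!r}")
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    source = os.fspath(source) if not isinstance(source, str) else source
    kwargs = dict(schema=format, preserve_underscores=True)
    if "\n" in source or ("(" in source and not os.path.exists(source)):
        trees = dendropy.TreeList.get(data=source, **kwargs)
        name = run_id or "run"
    else:
        trees = dendropy.TreeList.get(path=source, **kwargs)
        name = run_id or os.path.basename(source)
    if len(trees) == 0:
        raise ValueError("no trees found in input")
    topologies = [_topology_from_dendropy(t) for t in trees]
    first = topologies[0].leaves
    for t in topologies[1:]:
        if t.leaves != first:
            raise TaxonSetMismatchError("trees do not share a single taxon set")
    drop = int(len(topologies) * burnin_fraction)
    kept = topologies[drop:]
    if not kept:
        raise ValueError("burn-in removed every sample")
    return ChainTrace(
        run_id=name, topologies=kept, interval=interval, burnin_fraction=burnin_fraction
    )


@dataclass
class PosteriorSummary:
    """Topology -> count table over one or more runs, ordered by descending
    posterior probability with a deterministic tie rule."""

    counts: dict
    ordering: list
    total: int
    per_run: dict
    tie_rule: str
    seed: int | None = None

    def frequency(self, topology: Topology) -> float:
        return self.counts.get(topology, 0) / self.total

    @property
    def frequencies(self) -> dict:
        return {t: self.counts[t] / self.total for t in self.ordering}

    @property
    def map_tree(self) -> Topology:
        return self.ordering[0]

    @property
    def leaves(self) -> frozenset:
        return self.ordering[0].leaves

    def credible_set(self, level: float = 0.95) -> list:
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        out, cum = [], 0.0
        for t in self.ordering:
            out.append(t)
            cum += self.counts[t] / self.total
            if cum > level:
                break
        return out


def summarize(
    traces: Iterable[ChainTrace],
    tie_rule: str = "auto",
    seed: int = 0,
    random_tie_threshold: int = 10,
) -> PosteriorSummary:
    """Aggregate one or more chain traces into a posterior summary.

    Ordering is by descending count.  Ties are broken by first-appearance
    order in the concatenated traces ("sample-order"); under the default
    "auto" rule, ties are instead broken uniformly at random (seeded) when
    any tie group exceeds ``random_tie_threshold`` members, since sample
    order is biased when nearly every tree is sampled once or twice.
    """
    traces = list(traces)
    if not traces or any(len(t) == 0 for t in traces):
        raise ValueError("summarize needs at least one nonempty trace")
    if tie_rule not in ("sample-order", "random", "auto"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    counts: Counter = Counter()
    first_seen: dict = {}
    per_run: dict = {}
    pos = 0
    for trace in traces:
        run_counts: Counter = Counter()
        for t in trace:
            counts[t] += 1
            run_counts[t] += 1
            if t not in first_seen:
                first_seen[t] = pos
            pos += 1
        per_run[trace.run_id] = dict(run_counts)
    groups: dict[int, list] = defaultdict(list)
    for t in sorted(counts, key=lambda t: first_seen[t]):
        groups[counts[t]].append(t)
    use_random = tie_rule == "random" or (
        tie_rule == "auto"
        and any(len(g) > random_tie_threshold for g in groups.values())
    )
    rng = random.Random(seed)
    ordering = []
    for c in sorted(groups, reverse=True):
        group = groups[c]
        if use_random and len(group) > 1:
            rng.shuffle(group)
        ordering.extend(group)
    return PosteriorSummary(
        counts=dict(counts),
        ordering=ordering,
        total=sum(counts.values()),
        per_run=per_run,
        tie_rule="random" if use_random else "sample-order",
        seed=seed if use_random else None,
    )


def top_trees(summary: PosteriorSummary, m: int = 4096, level: float = 0.95) -> list:
    """The "top trees": the ``level`` credible set when it has fewer than
    ``m`` members, otherwise the first ``m`` trees of the ordering."""
    if m < 1:
        raise ValueError("m must be >= 1")
    credible = summary.credible_set(level)
    if len(credible) < m:
        return credible
    return summary.ordering[:m]


def resolution_count(k) -> int:
    """(2k-3)!!, the number of rooted binary shapes on k labeled leaves —
    the credible-set inflation factor contributed by a clade of k
    indistinguishable sequences.  An iterable of clade sizes yields the
    product of the per-clade factors."""
    if not isinstance(k, int):
        return math.prod(resolution_count(int(ki)) for ki in k)
    if k < 1:
        raise ValueError("clade size must be >= 1")
    if k <= 2:
        return 1
    return math.prod(range(2 * k - 3, 0, -2))


def write_summary_tsv(summary: PosteriorSummary, path) -> None:
    cum = 0.0
    with open(path, "w") as fh:
        fh.write("topology\tcount\tfrequency\tcumulative\n")
        for t in summary.ordering:
            f = summary.counts[t] / summary.total
            cum += f
            fh.write(f"{t.newick}\t{summary.counts[t]}\t{f!r}\t{cum!r}\n")
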