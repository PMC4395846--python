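"""Exact SPR and Robinson-Foulds distances between tree topologies.

The rooted SPR distance is computed through a maximum agreement forest
(MAF): a forest obtained by cutting edges from both (root-augmented) trees
so that the remaining components agree, cutting as few edges as possible.
The minimum number of cuts equals the rooted SPR distance.  The search is
the standard fixed-parameter scheme — iterative deepening on the number of
cuts k with three-way branching on an incompatible cherry (cut one leaf,
cut the other, or cut every subtree pendant on the path between them) —
whose cost grows exponentially in the distance but only linearly in tree
size, so distance-1 queries are near-instant.

No MAF characterization exists for the *unrooted* SPR distance, so it is
bounded from above by minimizing the rooted distance over rootings of the
two trees ("best rooting").  The bound is tight whenever the true distance
is one, which is all the SPR-graph machinery needs, and agrees with the
brute-force BFS distance on small trees except in rare pathological cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trees import Topology, nontrivial_splits

__all__ = [
    "RootedTopology",
    "AgreementForest",
    "DistanceMatrix",
    "ROOT_TOKEN",
    "all_rootings",
    "root_at_leaf",
    "rooted_spr_distance",
    "unrooted_spr_distance",
    "is_one_spr",
    "neighbors",
    "spr_neighborhood",
    "bfs_spr_distance",
    "cached_spr_distance",
    "rf_distance",
    "pairwise_matrix",
    "spr_path",
]

#: leaf token for the formal root handle added before the MAF search; the
#: augmented root prevents pruning through the root, which is required for
#: |MAF| - 1 to equal the rooted SPR distance.
ROOT_TOKEN = "__root__"


def _rmin(shape) -> str:
    while not isinstance(shape, str):
        shape = shape[0]
    return shape


def _rnode(a, b):
    return (a, b) if _rmin(a) <= _rmin(b) else (b, a)


@dataclass(frozen=True)
class RootedTopology:
    """A rooted binary leaf-labeled shape, as nested min-leaf-ordered
    2-tuples.  Obtained from an unrooted topology by rooting on an edge."""

    shape: tuple
    leaves: frozenset

    @classmethod
    def from_shape(cls, shape) -> "RootedTopology":
        return cls(shape=shape, leaves=frozenset(_riter(shape)))

    def __eq__(self, other) -> bool:
        return isinstance(other, RootedTopology) and self.shape == other.shape

    def __hash__(self) -> int:
        return hash(self.shape)


def _riter(shape):
    if isinstance(shape, str):
        yield shape
    else:
        yield from _riter(shape[0])
        yield from _riter(shape[1])


def _rooted_side(adj, labels, node, parent):
    if node in labels:
        return labels[node]
    kids = [w for w in adj[node] if w != parent]
    return _rnode(
        _rooted_side(adj, labels, kids[0], node),
        _rooted_side(adj, labels, kids[1], node),
    )


def all_rootings(t: Topology) -> list:
    """One rooted topology per edge of ``t`` (root placed on that edge)."""
    adj, labels = t.adjacency()
    out, seen = [], set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                shape = _rnode(
                    _rooted_side(adj, labels, u, v), _rooted_side(adj, labels, v, u)
                )
                if shape not in seen:
                    seen.add(shape)
                    out.append(RootedTopology.from_shape(shape))
    return out


def root_at_leaf(t: Topology, leaf: str) -> RootedTopology:
    """Root on the pendant edge of ``leaf``."""
    if leaf not in t.leaves:
        raise ValueError(f"leaf {leaf!r} not in topology")
    adj, labels = t.adjacency()
    node = next(n for n, lab in labels.items() if lab == leaf)
    (v,) = adj[node]
    return RootedTopology.from_shape(
        _rnode(leaf, _rooted_side(adj, labels, v, node))
    )


# ---------------------------------------------------------------------------
# MAF search.  Working representation: leaves are frozensets of original
# labels (cherry contraction merges labels by set union), internal nodes are
# plain 2-tuples; a forest is a list of such components.


def _fs_shape(shape):
    if isinstance(shape, str):
        return frozenset((shape,))
    return (_fs_shape(shape[0]), _fs_shape(shape[1]))


def _cherries(node, out):
    if isinstance(node, frozenset):
        return
    a, b = node
    if isinstance(a, frozenset) and isinstance(b, frozenset):
        out.append((a, b))
    else:
        _cherries(a, out)
        _cherries(b, out)


def _has_leaf(node, lab) -> bool:
    if isinstance(node, frozenset):
        return node == lab
    return _has_leaf(node[0], lab) or _has_leaf(node[1], lab)


def _sibling(node, lab):
    if isinstance(node, frozenset):
        return None
    a, b = node
    if a == lab:
        return b
    if b == lab:
        return a
    return _sibling(a, lab) or _sibling(b, lab)


def _cut(node, sub):
    """Remove subtree ``sub`` (matched by equality) and suppress its
    parent; ``node`` must properly contain ``sub``."""
    a, b = node
    if a == sub:
        return b
    if b == sub:
        return a
    if _contains(a, sub):
        return (_cut(a, sub), b)
    return (a, _cut(b, sub))


def _contains(node, sub) -> bool:
    if node == sub:
        return True
    if isinstance(node, frozenset):
        return False
    return _contains(node[0], sub) or _contains(node[1], sub)


def _contract(node, a, b, merged):
    if isinstance(node, frozenset):
        return node
    x, y = node
    if (x == a and y == b) or (x == b and y == a):
        return merged
    return (_contract(x, a, b, merged), _contract(y, a, b, merged))


def _path_pendants(node, a, b):
    """Subtrees pendant on the path between leaves a and b (both must be in
    ``node``); empty list means (a, b) is already a cherry."""

    def chain(n, lab):
        # pendant subtrees on the way down from n to leaf lab
        out = []
        while n != lab:
            x, y = n
            if _has_leaf(x, lab):
                out.append(y)
                n = x
            else:
                out.append(x)
                n = y
        return out

    n = node
    while True:
        if isinstance(n, frozenset):
            raise ValueError("path endpoints not below node")
        x, y = n
        ax, bx = _has_leaf(x, a), _has_leaf(x, b)
        if ax and bx:
            n = x
        elif not ax and not bx:
            n = y
        else:
            side_a, side_b = (x, y) if ax else (y, x)
            return chain(side_a, a) + chain(side_b, b)


def _maf_search(t1, comps, k, done):
    """k-bounded agreement-forest search; returns final component list or
    None.  ``done`` holds components already fully matched."""
    comps = list(comps)
    done = list(done)
    while True:
        # singleton components agree trivially: retire them
        retired = False
        for i, c in enumerate(comps):
            if isinstance(c, frozenset):
                if t1 == c:
                    return done + comps
                t1 = _cut(t1, c)
                done.append(comps.pop(i))
                retired = True
                break
        if retired:
            continue
        if isinstance(t1, frozenset):
            return done + comps
        # cherry contraction wherever both trees agree
        cherries: list = []
        _cherries(t1, cherries)
        contracted = False
        for a, b in cherries:
            i = next(j for j, c in enumerate(comps) if _has_leaf(c, a))
            if _sibling(comps[i], a) == b:
                merged = a | b
                t1 = _contract(t1, a, b, merged)
                comps[i] = merged if comps[i] == (a, b) or comps[i] == (b, a) else _contract(
                    comps[i], a, b, merged
                )
                contracted = True
                break
        if not contracted:
            break
    if k <= 0:
        return None
    a, b = cherries[0]
    ia = next(j for j, c in enumerate(comps) if _has_leaf(c, a))
    ib = next(j for j, c in enumerate(comps) if _has_leaf(c, b))
    for lab, idx in ((a, ia), (b, ib)):
        trial = comps[:idx] + [_cut(comps[idx], lab)] + comps[idx + 1 :] + [lab]
        result = _maf_search(t1, trial, k - 1, done)
        if result is not None:
            return result
    if ia == ib:
        pend = _path_pendants(comps[ia], a, b)
        if 0 < len(pend) <= k:
            c = comps[ia]
            for s in pend:
                c = _cut(c, s)
            trial = comps[:ia] + [c] + comps[ia + 1 :] + pend
            result = _maf_search(t1, trial, k - len(pend), done)
            if result is not None:
                return result
    return None


@dataclass(frozen=True)
class AgreementForest:
    """Certificate of a rooted SPR distance: the agreement-forest component
    leaf sets (the root component retains :data:`ROOT_TOKEN`), with
    ``len(components) - 1`` equal to the number of cut edges."""

    components: tuple
    n_cuts: int

    @property
    def root_component(self) -> frozenset:
        return next(c for c in self.components if ROOT_TOKEN in c)


def _component_leafset(comp) -> frozenset:
    if isinstance(comp, frozenset):
        return comp
    return _component_leafset(comp[0]) | _component_leafset(comp[1])


def _augment(rt: RootedTopology):
    return (_fs_shape(rt.shape), frozenset((ROOT_TOKEN,)))


def rooted_spr_distance(
    t1: RootedTopology,
    t2: RootedTopology,
    cap: int | None = None,
    certificate: bool = False,
):
    """Exact rooted SPR distance via a maximum agreement forest.

    With ``cap`` given, searches only up to ``cap`` cuts and returns None
    when the distance exceeds it (never a fabricated number).  With
    ``certificate=True`` returns ``(distance, AgreementForest)``.
    """
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    limit = 2 * len(t1.leaves) if cap is None else cap
    a1, a2 = _augment(t1), _augment(t2)
    for k in range(limit + 1):
        forest = _maf_search(a1, [a2], k, [])
        if forest is not None:
            if not certificate:
                return k
            comps = tuple(sorted(map(_component_leafset, forest), key=sorted))
            return k, AgreementForest(components=comps, n_cuts=k)
    return (None, None) if certificate else None


def _rooting_pairs(t1: Topology, t2: Topology, mode: str):
    if mode in ("all", "all-rootings"):
        return list(itertools.product(all_rootings(t1), all_rootings(t2)))
    if mode in ("leaf", "leaf-rootings"):
        return [
            (root_at_leaf(t1, leaf), root_at_leaf(t2, leaf))
            for leaf in sorted(t1.leaves)
        ]
    raise ValueError(f"unknown rooting mode {mode!r}")


def unrooted_spr_distance(
    t1: Topology, t2: Topology, mode: str = "all", cap: int | None = None
) -> Optional[int]:
    """Best-rooting SPR distance between unrooted topologies.

    ``mode="all"`` minimizes over independent root placements on every edge
    of each tree (the exact best-rooting distance); ``mode="leaf"``
    minimizes over rooting both trees at the same leaf, a cheaper upper
    bound that coincides with "all" at distance <= 1.  Returns None when a
    ``cap`` is given and exceeded.
    """
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    if t1 == t2:
        return 0
    pairs = _rooting_pairs(t1, t2, mode)
    limit = 2 * len(t1.leaves) if cap is None else cap
    for k in range(1, limit + 1):
        for r1, r2 in pairs:
            if _maf_search(_augment(r1), [_augment(r2)], k, []) is not None:
                return k
    return None


# ---------------------------------------------------------------------------
# rearrangement neighborhoods


def _copy_adj(adj):
    return {n: set(s) for n, s in adj.items()}


def _component(adj, start):
    seen = {start}
    stack = [start]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _edges_within(adj, nodes):
    return [(u, v) for u in nodes for v in adj[u] if v in nodes and u < v]


def _suppress(adj, node):
    a, b = adj.pop(node)
    adj[a].discard(node)
    adj[b].discard(node)
    adj[a].add(b)
    adj[b].add(a)
    return a, b


def _spr_variants(adj, labels):
    """Yield canonical topologies one SPR move away (may include the
    original; callers dedupe and drop it)."""
    fresh = max(adj) + 1
    for u in list(adj):
        if len(adj[u]) != 3:
            continue
        for v in list(adj[u]):
            # prune the subtree on the v side of edge (u, v)
            base = _copy_adj(adj)
            base[u].discard(v)
            base[v].discard(u)
            x, y = _suppress(base, u)
            main = _component(base, x)
            for p, q in _edges_within(base, main):
                if {p, q} == {x, y}:
                    continue  # reattaching on the suppressed edge restores t
                a2 = _copy_adj(base)
                w = fresh
                a2[p].discard(q)
                a2[q].discard(p)
                a2[w] = {p, q, v}
                a2[p].add(w)
                a2[q].add(w)
                a2[v].add(w)
                yield Topology.from_adjacency(a2, labels)


def _nni_variants(adj, labels):
    for u in adj:
        for v in adj[u]:
            if u < v and len(adj[u]) == 3 and len(adj[v]) == 3:
                (a, b) = [w for w in adj[u] if w != v]
                for c in [w for w in adj[v] if w != u]:
                    a2 = _copy_adj(adj)
                    a2[u].discard(b)
                    a2[b].discard(u)
                    a2[v].discard(c)
                    a2[c].discard(v)
                    a2[u].add(c)
                    a2[c].add(u)
                    a2[v].add(b)
                    a2[b].add(v)
                    yield Topology.from_adjacency(a2, labels)


def _tbr_variants(adj, labels):
    fresh = max(adj) + 1
    for u in list(adj):
        for v in list(adj[u]):
            if u > v:
                continue
            base = _copy_adj(adj)
            base[u].discard(v)
            base[v].discard(u)
            sides = []
            for end in (u, v):
                if len(base[end]) == 0:  # a detached leaf
                    sides.append((end, [None]))
                else:
                    a, b = _suppress(base, end)
                    comp = _component(base, a)
                    sides.append((None, _edges_within(base, comp)))
            (leaf_u, attach_u), (leaf_v, attach_v) = sides
            for e1 in attach_u:
                for e2 in attach_v:
                    a2 = _copy_adj(base)
                    ends = []
                    nxt = fresh
                    for leaf, e in ((leaf_u, e1), (leaf_v, e2)):
                        if e is None:
                            ends.append(leaf)
                        else:
                            p, q = e
                            w = nxt
                            nxt += 1
                            a2[p].discard(q)
                            a2[q].discard(p)
                            a2[w] = {p, q}
                            a2[p].add(w)
                            a2[q].add(w)
                            ends.append(w)
                    a2[ends[0]].add(ends[1])
                    a2[ends[1]].add(ends[0])
                    yield Topology.from_adjacency(a2, labels)


def neighbors(t: Topology, move: str = "spr") -> set:
    """All distinct topologies one NNI, SPR, or TBR move away from ``t``
    (excluding ``t`` itself).  nni-neighborhoods are subsets of spr, and
    spr of tbr."""
    if t.n_leaves < 4:
        raise ValueError("rearrangements need at least 4 leaves")
    gen = {"nni": _nni_variants, "spr": _spr_variants, "tbr": _tbr_variants}
    if move not in gen:
        raise ValueError(f"unknown move type {move!r}")
    adj, labels = t.adjacency()
    return {u for u in gen[move](adj, labels) if u != t}


_NEIGHBOR_CACHE: dict = {}


def spr_neighborhood(t: Topology) -> frozenset:
    """Cached SPR neighborhood; backbone of distance-1 edge detection and
    of the Metropolis kernels in :mod:`sprmix.synthetic`."""
    hood = _NEIGHBOR_CACHE.get(t.newick)
    if hood is None:
        hood = frozenset(neighbors(t, "spr"))
        _NEIGHBOR_CACHE[t.newick] = hood
    return hood


_DISTANCE_CACHE: dict = {}


def cached_spr_distance(t1: Topology, t2: Topology, mode: str = "leaf") -> int:
    """Memoized uncapped best-rooting distance; graph annotation and
    clustering hit the same pairs repeatedly."""
    if t1 == t2:
        return 0
    key = (mode,) + (
        (t1.newick, t2.newick) if t1.newick < t2.newick else (t2.newick, t1.newick)
    )
    d = _DISTANCE_CACHE.get(key)
    if d is None:
        d = unrooted_spr_distance(t1, t2, mode=mode)
        _DISTANCE_CACHE[key] = d
    return d


def is_one_spr(t1: Topology, t2: Topology) -> bool:
    """True iff the unrooted SPR distance is exactly 1 (the SPR-graph edge
    predicate)."""
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    return t1 != t2 and t2 in spr_neighborhood(t1)


def bfs_spr_distance(t1: Topology, t2: Topology, cap: int = 3) -> Optional[int]:
    """Exact unrooted SPR distance by breadth-first search over SPR
    neighborhoods.  Independent of the MAF machinery; intended as an oracle
    for small trees (<= ~8 taxa or small caps).  None when > cap."""
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    if t1 == t2:
        return 0
    frontier = {t1}
    visited = {t1}
    for depth in range(1, cap + 1):
        nxt = set()
        for t in frontier:
            for u in spr_neighborhood(t):
                if u == t2:
                    return depth
                if u not in visited:
                    visited.add(u)
                    nxt.add(u)
        frontier = nxt
    return None


def spr_path(t1: Topology, t2: Topology, cap: int = 3) -> list:
    """A shortest SPR path t1 = s0, s1, ..., sd = t2 (consecutive trees at
    distance 1), found by BFS with predecessor reconstruction.  Raises if
    the distance exceeds ``cap``."""
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    if t1 == t2:
        return [t1]
    prev = {t1: None}
    frontier = [t1]
    for _ in range(cap):
        nxt = []
        for t in frontier:
            for u in spr_neighborhood(t):
                if u not in prev:
                    prev[u] = t
                    if u == t2:
                        path = [u]
                        while prev[path[-1]] is not None:
                            path.append(prev[path[-1]])
                        return path[::-1]
                    nxt.append(u)
        frontier = nxt
    raise ValueError(f"no SPR path within cap={cap}")


def rf_distance(t1: Topology, t2: Topology) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    nontrivial bipartition sets."""
    if t1.leaves != t2.leaves:
        raise ValueError("leaf-set mismatch")
    return len(nontrivial_splits(t1) ^ nontrivial_splits(t2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered topology list.
    Entries above a cap are None (written as NA), never a guessed value."""

    trees: list
    matrix: list
    metric: str
    cap: int | None = None

    def to_array(self) -> np.ndarray:
        return np.array(
            [[np.nan if d is None else d for d in row] for row in self.matrix]
        )

    def write_tsv(self, path) -> None:
        n = len(self.trees)
        with open(path, "w") as fh:
            fh.write("\t".join([""] + [str(i) for i in range(n)]) + "\n")
            for i, row in enumerate(self.matrix):
                cells = ["NA" if d is None else str(d) for d in row]
                fh.write("\t".join([str(i)] + cells) + "\n")


def pairwise_matrix(
    trees: list,
    metric: str = "spr",
    cap: int | None = None,
    mode: str = "all",
) -> DistanceMatrix:
    """Pairwise SPR or RF distances (the RSPR-style matrix that feeds MDS
    and graph construction).  For SPR with ``cap=1`` only the distance-1
    predicate is computed, via neighborhood hashing."""
    trees = list(trees)
    leafset = trees[0].leaves
    if any(t.leaves != leafset for t in trees):
        raise ValueError("mixed leaf sets")
    n = len(trees)
    matrix = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if trees[i] == trees[j]:
                d = 0
            elif metric == "rf":
                d = rf_distance(trees[i], trees[j])
            elif metric == "spr" and cap == 1:
                d = 1 if trees[j] in spr_neighborhood(trees[i]) else None
            elif metric == "spr":
                d = unrooted_spr_distance(trees[i], trees[j], mode=mode, cap=cap)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            matrix[i][j] = matrix[j][i] = d
    return DistanceMatrix(trees=trees, matrix=matrix, metric=metric, cap=cap)
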