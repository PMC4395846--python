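"""Ground-truth tree-space targets and Metropolis chain traces.

Real multimodal ("peaky") topology posteriors consist of clouds of high
probability trees around a few center topologies, separated by valleys of
improbable intermediates.  This module builds explicit target
distributions with that shape — k peak centers at chosen SPR separations,
per-peak weights, and probability decaying geometrically with SPR distance
from the nearest center — and runs Metropolis-Hastings samplers over
topology space against them, so every statistic in the package can be
exercised with known ground truth and no external MCMC software.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .trees import ChainTrace, Topology
from .spr import spr_neighborhood, spr_path, unrooted_spr_distance

__all__ = [
    "PeakySpec",
    "PeakyTarget",
    "random_topology",
    "random_spr_move",
    "enumerate_topologies",
    "spr_ball",
    "make_peaky_target",
    "simulate_chain",
    "sample_iid",
    "write_nexus_trace",
]


def _default_labels(n: int) -> list:
    width = len(str(n))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def random_topology(n: int, seed=None, labels=None) -> Topology:
    """A uniform random unrooted binary topology on n >= 4 leaves, built by
    sequential random leaf attachment (uniform over the (2n-5)!! shapes)."""
    if n < 4:
        raise ValueError("need at least 4 taxa")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    labels = labels if labels is not None else _default_labels(n)
    if len(labels) != n:
        raise ValueError("label count does not match n")
    adj: dict[int, set] = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    leaf_labels = {1: labels[0], 2: labels[1], 3: labels[2]}
    nxt = 4
    for label in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = rng.choice(edges)
        w, leaf = nxt, nxt + 1
        nxt += 2
        adj[u].discard(v)
        adj[v].discard(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
        leaf_labels[leaf] = label
    return Topology.from_adjacency(adj, leaf_labels)


def random_spr_move(t: Topology, rng: random.Random) -> Topology:
    """A uniformly chosen topology-changing SPR rearrangement of ``t``
    (uniform over the distinct neighbor topologies)."""
    return rng.choice(sorted(spr_neighborhood(t)))


def enumerate_topologies(labels) -> list:
    """All (2n-5)!! unrooted binary topologies on the given labels, by
    exhaustive sequential attachment.  Exponential: keep n small."""
    labels = sorted(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 taxa")

    def grow(shapes, remaining):
        if not remaining:
            return shapes
        label = remaining[0]
        out = set()
        for t in shapes:
            adj, leaf_labels = t.adjacency()
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            nxt = max(adj) + 2
            for u, v in edges:
                a2 = {k: set(s) for k, s in adj.items()}
                w, leaf = nxt, nxt + 1
                a2[u].discard(v)
                a2[v].discard(u)
                a2[w] = {u, v, leaf}
                a2[u].add(w)
                a2[v].add(w)
                a2[leaf] = {w}
                out.add(Topology.from_adjacency(a2, {**leaf_labels, leaf: label}))
        return grow(sorted(out), remaining[1:])

    a, b, c, d = labels[:4]
    base = [
        Topology.from_newick(f"(({a},{b}),({c},{d}));"),
        Topology.from_newick(f"(({a},{c}),({b},{d}));"),
        Topology.from_newick(f"(({a},{d}),({b},{c}));"),
    ]
    return grow(base, labels[4:])


def spr_ball(center: Topology, radius: int) -> dict:
    """BFS enumeration of the SPR ball: topology -> SPR distance from the
    center, for all topologies within ``radius`` moves."""
    out = {center: 0}
    frontier = [center]
    for d in range(1, radius + 1):
        nxt = []
        for t in frontier:
            for u in spr_neighborhood(t):
                if u not in out:
                    out[u] = d
                    nxt.append(u)
        frontier = nxt
    return out


@dataclass
class PeakySpec:
    """Recipe for a multimodal topology target.

    ``centers`` may be given explicitly; otherwise ``k`` centers are drawn
    at pairwise best-rooting SPR separation ``separation`` from a seeded
    random walk.  Probability within a peak decays as weight * decay**d
    with d the SPR distance to the nearest center, truncated at ``radius``.
    ``bridge_mass`` > 0 additionally places that much total mass, spread
    evenly, on the interior topologies of shortest SPR paths between
    consecutive centers — the valley construction that keeps the 1-SPR
    Metropolis kernel's support connected while making crossings rare.
    """

    n_taxa: int = 8
    k: int = 2
    separation: int = 4
    weights: tuple = (0.8, 0.2)
    decay: float = 0.1
    radius: int = 1
    bridge_mass: float = 0.0
    centers: list | None = None
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("peak weights must sum to 1")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if not 0.0 <= self.bridge_mass < 1.0:
            raise ValueError("bridge_mass must be in [0, 1)")


@dataclass
class PeakyTarget:
    """A realized target distribution with its generator ground truth."""

    probabilities: dict  # Topology -> probability (sums to 1)
    centers: list
    peak_of: dict  # Topology -> peak index (bridge trees: -1)
    bridge: list
    merged_peaks: bool  # True when peak balls overlapped

    @property
    def support(self) -> list:
        return list(self.probabilities)

    def peak_mass(self, i: int) -> float:
        return sum(
            p for t, p in self.probabilities.items() if self.peak_of[t] == i
        )


def _walk_out(origin: Topology, s: int, rng: random.Random):
    """Greedy outward SPR walk: step i moves to a neighbor at (leaf-rooting)
    SPR distance exactly i from the origin.  Random walks collapse back
    toward the origin, so the walk is steered instead."""
    cur = origin
    path = []
    for i in range(1, s + 1):
        nbrs = sorted(spr_neighborhood(cur))
        rng.shuffle(nbrs)
        for cand in nbrs:
            if unrooted_spr_distance(origin, cand, mode="leaf", cap=i) == i:
                cur = cand
                path.append(cand)
                break
        else:
            return None
    return path


def _draw_centers(spec: PeakySpec, rng: random.Random):
    """Draw peak centers at the requested separation; returns the centers
    plus, for each consecutive pair, the interior of the shortest SPR path
    traced by the placing walk (reused as the bridge)."""
    centers = [random_topology(spec.n_taxa, rng)]
    paths = []
    while len(centers) < spec.k:
        for _ in range(50):
            walk = _walk_out(centers[-1], spec.separation, rng)
            if walk is None:
                continue
            cand = walk[-1]
            d = unrooted_spr_distance(
                centers[-1], cand, mode="all", cap=spec.separation
            )
            others_ok = all(
                unrooted_spr_distance(c, cand, mode="all", cap=spec.separation - 1)
                is None
                for c in centers[:-1]
            )
            if d == spec.separation and others_ok:
                centers.append(cand)
                paths.append(walk[:-1])
                break
        else:
            raise RuntimeError("could not place peak centers at the separation")
    return centers, paths


def make_peaky_target(spec: PeakySpec) -> PeakyTarget:
    """Materialize the target distribution of a :class:`PeakySpec`."""
    rng = random.Random(spec.seed)
    paths = None
    if spec.centers is not None:
        centers = list(spec.centers)
        if len(centers) != len(spec.weights):
            raise ValueError("centers and weights length mismatch")
    else:
        if spec.k != len(spec.weights):
            raise ValueError("k and weights length mismatch")
        centers, paths = _draw_centers(spec, rng)
    balls = [spr_ball(c, spec.radius) for c in centers]
    # nearest-center assignment; ties and overlaps go to the earlier peak
    peak_of: dict = {}
    dist_of: dict = {}
    merged = False
    for i, ball in enumerate(balls):
        for t, d in ball.items():
            if t in peak_of and peak_of[t] != i:
                merged = True
                if d < dist_of[t]:
                    peak_of[t], dist_of[t] = i, d
            elif t not in peak_of:
                peak_of[t], dist_of[t] = i, d

    bridge = []
    if spec.bridge_mass > 0 and len(centers) > 1:
        if paths is not None:
            interiors = paths
        else:
            interiors = [
                spr_path(a, b, cap=spec.separation + 1)[1:-1]
                for a, b in zip(centers, centers[1:])
            ]
        for interior in interiors:
            bridge.extend(t for t in interior if t not in peak_of)
        for t in bridge:
            peak_of[t], dist_of[t] = -1, None

    peak_scale = 1.0 - (spec.bridge_mass if bridge else 0.0)
    probs: dict = {}
    for i in range(len(centers)):
        members = [t for t in peak_of if peak_of[t] == i]
        z = sum(spec.decay ** dist_of[t] for t in members)
        for t in members:
            probs[t] = peak_scale * spec.weights[i] * spec.decay ** dist_of[t] / z
    for t in bridge:
        probs[t] = spec.bridge_mass / len(bridge)
    return PeakyTarget(
        probabilities=probs,
        centers=centers,
        peak_of=peak_of,
        bridge=bridge,
        merged_peaks=merged,
    )


class DisconnectedSupportError(ValueError):
    """The target support is not connected under the proposal kernel."""


def _check_connected(support, reach) -> None:
    seen = {support[0]}
    stack = [support[0]]
    supportset = set(support)
    while stack:
        t = stack.pop()
        for u in reach(t):
            if u in supportset and u not in seen:
                seen.add(u)
                stack.append(u)
    if len(seen) != len(supportset):
        raise DisconnectedSupportError(
            f"kernel reaches only {len(seen)} of {len(supportset)} support trees"
        )


def simulate_chain(
    target,
    steps: int,
    seed: int = 0,
    kernel: str = "spr1",
    p2: float = 0.2,
    interval: int = 1,
    n_runs: int = 1,
    run_prefix: str = "run",
    start=None,
) -> list:
    """Metropolis-Hastings sampling of a topology target distribution.

    ``target`` is a :class:`PeakyTarget` or a plain topology->probability
    dict.  The ``spr1`` kernel proposes a uniform SPR neighbor; ``spr-mix``
    proposes, with probability ``p2``, a uniform neighbor of a uniform
    neighbor (a 2-step SPR jump, the desk-scale stand-in for a Metropolis-
    coupled hot chain).  Proposal asymmetry is corrected exactly with the
    true neighborhood sizes, so detailed balance holds; off-support
    proposals are rejected outright.  Each of the ``n_runs`` pseudo-
    independent runs starts at a draw from the target (an overdispersed
    start across peaks) and records every ``interval``-th state.
    """
    probs = target.probabilities if isinstance(target, PeakyTarget) else dict(target)
    if kernel not in ("spr1", "spr-mix"):
        raise ValueError(f"unknown kernel {kernel!r}")
    support = sorted(probs)
    two_step = kernel == "spr-mix"

    def reach(t):
        hood = spr_neighborhood(t)
        if not two_step:
            return hood
        out = set(hood)
        for z in hood:
            out |= spr_neighborhood(z)
        return out - {t}

    _check_connected(support, reach)

    size_cache: dict = {}
    sorted_cache: dict = {}

    def hood_size(t) -> int:
        s = size_cache.get(t)
        if s is None:
            s = len(spr_neighborhood(t))
            size_cache[t] = s
        return s

    def sorted_hood(t):
        h = sorted_cache.get(t)
        if h is None:
            h = sorted(spr_neighborhood(t))
            sorted_cache[t] = h
        return h

    def q(x, y) -> float:
        # exact proposal density of the (mixed) kernel
        hx = spr_neighborhood(x)
        q1 = (1.0 / len(hx)) if y in hx else 0.0
        if not two_step:
            return q1
        hy = spr_neighborhood(y)
        q2 = sum(1.0 / hood_size(z) for z in hx & hy) / len(hx)
        return (1.0 - p2) * q1 + p2 * q2

    traces = []
    master = random.Random(seed)
    for r in range(n_runs):
        rng = random.Random(master.randrange(2**31))
        state = start if start is not None else rng.choices(
            support, weights=[probs[t] for t in support]
        )[0]
        samples = []
        for step in range(steps):
            hood = sorted_hood(state)
            if two_step and rng.random() < p2:
                mid = rng.choice(hood)
                prop = rng.choice(sorted_hood(mid))
            else:
                prop = rng.choice(hood)
            pi_y = probs.get(prop, 0.0)
            if pi_y > 0.0 and prop != state:
                ratio = pi_y * q(prop, state) / (probs[state] * q(state, prop))
                if ratio >= 1.0 or rng.random() < ratio:
                    state = prop
            if step % interval == 0:
                samples.append(state)
        traces.append(
            ChainTrace(
                run_id=f"{run_prefix}{r + 1}",
                topologies=samples,
                interval=interval,
            )
        )
    return traces


def sample_iid(
    target, n: int, seed: int = 0, n_runs: int = 1, run_prefix: str = "iid"
) -> list:
    """Independent draws from a target distribution, packaged as traces.

    This is the perfectly mixed reference sampler: summaries built from it
    estimate the target's probabilities with plain multinomial error, so
    structure recovery (graph components, clusters, CCD consistency) can be
    tested separately from Markov-chain dynamics.
    """
    probs = target.probabilities if isinstance(target, PeakyTarget) else dict(target)
    support = sorted(probs)
    weights = [probs[t] for t in support]
    master = random.Random(seed)
    traces = []
    for r in range(n_runs):
        rng = random.Random(master.randrange(2**31))
        traces.append(
            ChainTrace(
                run_id=f"{run_prefix}{r + 1}",
                topologies=rng.choices(support, weights=weights, k=n),
                interval=1,
            )
        )
    return traces


def write_nexus_trace(trace: ChainTrace, path) -> None:
    """Write a trace as a MrBayes-style Nexus .t file (TRANSLATE block,
    one tree per retained sample), so file-based pipelines can be fed."""
    taxa = sorted(trace.leaves)
    number = {lab: i + 1 for i, lab in enumerate(taxa)}

    def translated(shape):
        if isinstance(shape, str):
            return str(number[shape])
        return "(" + ",".join(translated(s) for s in shape) + ")"

    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin trees;\n   translate\n")
        for i, lab in enumerate(taxa):
            sep = "," if i < len(taxa) - 1 else ";"
            fh.write(f"      {i + 1} {lab}{sep}\n")
        for i, t in enumerate(trace.topologies):
            gen = (i + 1) * trace.interval
            fh.write(f"   tree gen.{gen} = [&U] {translated(t.shape)};\n")
        fh.write("end;\n")
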