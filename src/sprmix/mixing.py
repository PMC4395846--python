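"""Empirical tree-space mixing statistics from MCMC chain traces.

Mean access time (MAT) between two topologies is the mean number of
iterations the chain needs to first reach one from an occurrence of the
other; the mean commute time (MCT) of a tree is the sum of the MATs from
the MAP tree to it and back; the round-trip cover time is the mean number
of iterations needed to visit every top tree starting from, and returning
to, the MAP tree.  All estimators are right-censored at the end of the
trace: start occurrences with no completion are dropped and counted, never
reported as zero.  Times are reported in iterations (sample-step
differences times the sampling interval).

Each statistic has a linear single-pass implementation (running weighted
means / two-pointer sweeps) that agrees exactly with its naive quadratic
definition; the test suite checks this on random traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .trees import ChainTrace, Topology

__all__ = [
    "AccessEstimate",
    "MixingReport",
    "mean_access_times",
    "commute_times",
    "round_trip_cover_time",
    "transition_graph",
    "write_mixing_tsv",
    "OTHER",
]

OTHER = "__other__"


@dataclass(frozen=True)
class AccessEstimate:
    """A censored mean-time estimate: ``mean_iterations`` is None when no
    complete observation exists (``n_obs`` = 0)."""

    mean_iterations: float | None
    n_obs: int
    n_censored: int

    @property
    def available(self) -> bool:
        return self.n_obs > 0


def _check_reference(trace: ChainTrace, reference: Topology) -> None:
    if reference not in trace.topologies:
        raise ValueError("reference topology never occurs in the trace")


def mean_access_times(trace: ChainTrace, targets, reference: Topology):
    """MAT(reference -> j) and MAT(j -> reference) for every target j.

    Returns ``(from_ref, to_ref)`` dicts of :class:`AccessEstimate`.  The
    forward direction uses a running-weighted-mean pass: when j occurs, all
    reference occurrences not yet matched to a j are closed at once using
    prefix counts and index sums.  The reverse direction uses a next-
    occurrence sweep for the reference.  Both are O(n + targets).
    """
    _check_reference(trace, reference)
    targets = list(targets)
    seq = trace.topologies
    n = len(seq)
    iota = trace.interval

    # --- reference -> j ---
    ref_count, ref_sum = 0, 0
    seen_count = {t: 0 for t in targets}
    seen_sum = {t: 0 for t in targets}
    gap_sum = {t: 0 for t in targets}
    matched = {t: 0 for t in targets}
    for i, x in enumerate(seq):
        if x in seen_count:
            newly = ref_count - seen_count[x]
            if newly:
                gap_sum[x] += newly * i - (ref_sum - seen_sum[x])
                matched[x] += newly
            seen_count[x] = ref_count
            seen_sum[x] = ref_sum
        if x == reference:
            ref_count += 1
            ref_sum += i
    from_ref = {}
    for t in targets:
        censored = ref_count - seen_count[t]
        from_ref[t] = AccessEstimate(
            mean_iterations=iota * gap_sum[t] / matched[t] if matched[t] else None,
            n_obs=matched[t],
            n_censored=censored,
        )

    # --- j -> reference ---
    next_ref = [None] * (n + 1)
    for i in range(n - 1, -1, -1):
        next_ref[i] = i if seq[i] == reference else next_ref[i + 1]
    gap_sum2 = {t: 0 for t in targets}
    matched2 = {t: 0 for t in targets}
    censored2 = {t: 0 for t in targets}
    targetset = set(targets)
    for i, x in enumerate(seq):
        if x in targetset:
            nr = next_ref[i + 1]
            if nr is None:
                censored2[x] += 1
            else:
                gap_sum2[x] += nr - i
                matched2[x] += 1
    to_ref = {
        t: AccessEstimate(
            mean_iterations=iota * gap_sum2[t] / matched2[t] if matched2[t] else None,
            n_obs=matched2[t],
            n_censored=censored2[t],
        )
        for t in targets
    }
    return from_ref, to_ref


@dataclass
class MixingReport:
    """Per-topology access and commute times plus the round-trip cover
    time for one chain trace."""

    reference: Topology
    interval: int
    from_map: dict
    to_map: dict
    commute: dict
    cover: AccessEstimate

    def mct(self, t: Topology) -> float | None:
        return self.commute[t].mean_iterations


def commute_times(trace: ChainTrace, top: list) -> MixingReport:
    """Commute times MCT(j) = MAT(MAP -> j) + MAT(j -> MAP) for every top
    tree j (the MAP tree is the first of ``top``); unavailable whenever
    either leg is."""
    if not top:
        raise ValueError("empty top-tree list")
    reference = top[0]
    from_map, to_map = mean_access_times(trace, top, reference)
    commute = {}
    for t in top:
        a, b = from_map[t], to_map[t]
        commute[t] = AccessEstimate(
            mean_iterations=(
                a.mean_iterations + b.mean_iterations if a.available and b.available else None
            ),
            n_obs=min(a.n_obs, b.n_obs),
            n_censored=max(a.n_censored, b.n_censored),
        )
    return MixingReport(
        reference=reference,
        interval=trace.interval,
        from_map=from_map,
        to_map=to_map,
        commute=commute,
        cover=round_trip_cover_time(trace, top),
    )


def round_trip_cover_time(trace: ChainTrace, top: list) -> AccessEstimate:
    """Mean iterations to visit every top tree and return to the MAP tree.

    For each occurrence of the MAP tree at step t, the completion is the
    smallest t' > t with trace[t'] = MAP and every top tree present in
    steps t..t'.  All MAP occurrences start a (possibly overlapping)
    observation window.  Computed with a monotone two-pointer sweep.
    """
    if not top:
        raise ValueError("empty top-tree list")
    reference = top[0]
    _check_reference(trace, reference)
    seq = trace.topologies
    n = len(seq)
    topset = set(top)
    starts = [i for i, x in enumerate(seq) if x == reference]
    counts = {t: 0 for t in top}
    missing = len(top)
    lo = 0  # window is seq[lo..hi]
    hi = -1
    total, n_obs, n_censored = 0, 0, 0
    for s in starts:
        while lo < s:
            if lo <= hi:
                x = seq[lo]
                if x in topset:
                    counts[x] -= 1
                    if counts[x] == 0:
                        missing += 1
            lo += 1
        if hi < lo - 1:
            hi = lo - 1
        found = None
        # the inherited window [s, hi] may already be a minimal completion
        if missing == 0 and hi > s and seq[hi] == reference:
            found = hi
        # otherwise extend until covered *and* on a MAP occurrence past s
        j = hi
        while found is None and j + 1 < n:
            j += 1
            x = seq[j]
            if x in topset:
                if counts[x] == 0:
                    missing -= 1
                counts[x] += 1
            if missing == 0 and x == reference and j > s:
                found = j
        if found is None:
            hi = j
        if found is not None:
            total += found - s
            n_obs += 1
            hi = found
        else:
            n_censored += 1
    return AccessEstimate(
        mean_iterations=trace.interval * total / n_obs if n_obs else None,
        n_obs=n_obs,
        n_censored=n_censored,
    )


def transition_graph(trace: ChainTrace, top: list) -> nx.Graph:
    """Weighted MCMC transition graph: nodes are the top trees plus an
    "other" sink for everything else; undirected edges are weighted by the
    number of successive-sample transitions, and self-transitions are
    recorded as per-node ``dwell`` counts."""
    g = nx.Graph()
    topset = set(top)
    for i, t in enumerate(top):
        g.add_node(t, index=i, dwell=0)
    g.add_node(OTHER, dwell=0)

    def key(x):
        return x if x in topset else OTHER

    seq = trace.topologies
    for a, b in zip(seq, seq[1:]):
        ka, kb = key(a), key(b)
        if a == b or (ka == OTHER and kb == OTHER):
            g.nodes[ka]["dwell"] += 1
        elif g.has_edge(ka, kb):
            g[ka][kb]["weight"] += 1
        else:
            g.add_edge(ka, kb, weight=1)
    return g


def write_mixing_tsv(report: MixingReport, summary, path) -> None:
    def fmt(est: AccessEstimate) -> str:
        return "NA" if not est.available else repr(est.mean_iterations)

    with open(path, "w") as fh:
        fh.write(
            "topology\tprobability\tmat_from_map\tmat_to_map\tmct\t"
            "n_from\tn_to\tn_censored_from\tn_censored_to\n"
        )
        for t in report.commute:
            a, b = report.from_map[t], report.to_map[t]
            fh.write(
                f"{t.newick}\t{summary.frequency(t)!r}\t{fmt(a)}\t{fmt(b)}\t"
                f"{fmt(report.commute[t])}\t{a.n_obs}\t{b.n_obs}\t"
                f"{a.n_censored}\t{b.n_censored}\n"
            )
        fh.write(
            f"#round_trip_cover\t{fmt(report.cover)}\t"
            f"n={report.cover.n_obs}\tcensored={report.cover.n_censored}\n"
        )
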