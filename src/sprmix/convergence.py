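"""Convergence diagnostics over independent MCMC runs.

Two families: split-frequency diagnostics (the average standard deviation
of split frequencies, ASDSF, restricted to splits exceeding a minimum
frequency in at least one run; and max/RMS error of split frequencies
against a reference table), and a discrete topological analog of the
Gelman-Rubin potential scale reduction factor.  There is no sample mean
for topologies, so the topological variant replaces variances with mean
square *distance* deviations:

    s_i^2 = 1/(n(n-1)) sum_{j1,j2} d(x_{i j1}, x_{i j2})^2
    W     = mean_i s_i^2
    B     = 1/((m-1) m n^2) sum_{i1,i2,j1,j2} d(x_{i1 j1}, x_{i2 j2})^2
    V^    = (1 - 1/n) W + (1/n) B,      R^ = V^ / W

so sqrt(V^) estimates the topology root-mean-square deviation, and R^
approaches 1 as the runs converge to a common topology distribution.
Identical-topology comparisons are grouped: one distance per distinct
pair, squared and weighted by the product of sample counts.  Comparisons
may be restricted to the top trees, in which case every normalizer uses
the number of included comparisons rather than n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import Topology, nontrivial_splits
from .spr import rf_distance, unrooted_spr_distance

__all__ = [
    "SplitTable",
    "TopoGRReport",
    "split_table",
    "asdsf",
    "split_error",
    "topological_psrf",
]


@dataclass
class SplitTable:
    """Nontrivial split -> per-run frequency.  Splits are canonical leaf
    subsets (the block containing the smallest taxon)."""

    run_ids: list
    frequencies: dict  # split -> tuple of per-run frequencies
    n_per_run: list
    taxa: list

    @property
    def m(self) -> int:
        return len(self.run_ids)

    def mean_frequency(self, split) -> float:
        return sum(self.frequencies[split]) / self.m

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("split\t" + "\t".join(self.run_ids) + "\n")
            order = sorted(self.frequencies, key=lambda s: (-self.mean_frequency(s), sorted(s)))
            for split in order:
                mask = "".join("1" if t in split else "0" for t in self.taxa)
                fh.write(mask + "\t" + "\t".join(repr(f) for f in self.frequencies[split]) + "\n")


def split_table(runs) -> SplitTable:
    runs = list(runs)
    leaves = runs[0].leaves
    if any(r.leaves != leaves for r in runs):
        raise ValueError("runs do not share a taxon set")
    per_run = []
    for run in runs:
        counts: dict = {}
        for t in run:
            for s in nontrivial_splits(t):
                counts[s] = counts.get(s, 0) + 1
        per_run.append({s: c / len(run) for s, c in counts.items()})
    all_splits = set().union(*per_run)
    freqs = {s: tuple(fr.get(s, 0.0) for fr in per_run) for s in all_splits}
    return SplitTable(
        run_ids=[r.run_id for r in runs],
        frequencies=freqs,
        n_per_run=[len(r) for r in runs],
        taxa=sorted(leaves),
    )


def asdsf(runs, min_freq: float = 0.10, sd: str = "sample"):
    """Average standard deviation of split frequencies across runs.

    Only splits whose frequency exceeds ``min_freq`` in at least one run
    enter the average (MrBayes convention, default 10%).  ``sd`` selects
    the sample (n-1) or population standard deviation across runs.
    Returns ``(asdsf_value, SplitTable)``; the value is 0 when no split
    passes the filter.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("ASDSF needs at least 2 runs")
    if sd not in ("sample", "population"):
        raise ValueError(f"unknown sd convention {sd!r}")
    table = split_table(runs)
    m = table.m
    denom = m - 1 if sd == "sample" else m
    sds = []
    for split, freqs in table.frequencies.items():
        if max(freqs) > min_freq:
            mean = sum(freqs) / m
            sds.append(math.sqrt(sum((f - mean) ** 2 for f in freqs) / denom))
    return (sum(sds) / len(sds) if sds else 0.0), table


def _as_mean_table(x) -> dict:
    table = x if isinstance(x, SplitTable) else split_table(x)
    return {s: table.mean_frequency(s) for s in table.frequencies}


def split_error(runs_or_table, reference: SplitTable):
    """Max absolute error and RMSD of (mean) split frequencies against a
    reference table, over the union of nontrivial splits in either."""
    mine = _as_mean_table(runs_or_table)
    ref = {s: reference.mean_frequency(s) for s in reference.frequencies}
    splits = set(mine) | set(ref)
    if not splits:
        return 0.0, 0.0
    diffs = [mine.get(s, 0.0) - ref.get(s, 0.0) for s in splits]
    max_err = max(abs(d) for d in diffs)
    rmsd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    return max_err, rmsd


@dataclass
class TopoGRReport:
    W: float
    B: float
    V_hat: float
    R_hat: float
    rmsd: float  # sqrt(V_hat), the topology RMSD estimate
    n_per_chain: list
    m: int
    top_size: int | None
    metric: str

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("W\tB\tV_hat\tR_hat\trmsd\tm\tn_per_chain\ttop_size\tmetric\n")
            fh.write(
                f"{self.W!r}\t{self.B!r}\t{self.V_hat!r}\t{self.R_hat!r}\t"
                f"{self.rmsd!r}\t{self.m}\t{','.join(map(str, self.n_per_chain))}\t"
                f"{self.top_size}\t{self.metric}\n"
            )


def topological_psrf(
    runs,
    top: list | None = None,
    metric: str = "spr",
    distance_mode: str = "leaf",
    use_sqrt: bool = False,
    _distance_cache: dict | None = None,
) -> TopoGRReport:
    """Topological Gelman-Rubin-like PSRF over >= 2 independent runs.

    With ``top`` given, comparisons are restricted to the top trees and
    normalized by the number of included comparisons (N_i = in-top sample
    count of chain i); with ``top=None`` every sampled topology is
    included, which coincides with the restricted form when all samples
    are top trees.  Degenerate cases: W = B = 0 gives R^ = 1; W = 0 with
    B > 0 gives R^ = +inf (reported, not raised).  ``use_sqrt`` switches
    R^ to the classical sqrt(V^/W) form.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if metric not in ("spr", "rf"):
        raise ValueError(f"unknown metric {metric!r}")
    topset = None if top is None else set(top)
    chain_counts = []
    for run in runs:
        counts: dict = {}
        for t in run:
            if topset is None or t in topset:
                counts[t] = counts.get(t, 0) + 1
        chain_counts.append(counts)
    Ns = [sum(c.values()) for c in chain_counts]
    if all(N == 0 for N in Ns):
        raise ValueError("no samples fall in the top-tree set")
    m = len(runs)

    cache = {} if _distance_cache is None else _distance_cache

    def dist2(u: Topology, v: Topology) -> float:
        if u == v:
            return 0.0
        key = (u.newick, v.newick) if u.newick < v.newick else (v.newick, u.newick)
        d = cache.get(key)
        if d is None:
            d = (
                unrooted_spr_distance(u, v, mode=distance_mode)
                if metric == "spr"
                else rf_distance(u, v)
            )
            cache[key] = d
        return float(d * d)

    # within-chain mean square deviation, grouped by distinct topology
    s2 = []
    for counts, N in zip(chain_counts, Ns):
        if N < 2:
            s2.append(0.0)
            continue
        tot = 0.0
        items = list(counts.items())
        for a in range(len(items)):
            u, cu = items[a]
            for b in range(a + 1, len(items)):
                v, cv = items[b]
                tot += 2.0 * cu * cv * dist2(u, v)
        s2.append(tot / (N * (N - 1)))
    W = sum(s2) / m

    # between: every ordered chain pair (including i1 == i2)
    num = 0.0
    for i1 in range(m):
        for i2 in range(m):
            for u, cu in chain_counts[i1].items():
                for v, cv in chain_counts[i2].items():
                    if u != v:
                        num += cu * cv * dist2(u, v)
    pair_norm = sum(Ns[i1] * Ns[i2] for i1 in range(m) for i2 in range(m))
    B = num / ((m - 1) / m * pair_norm)

    n_bar = sum(Ns) / m
    V_hat = (1.0 - 1.0 / n_bar) * W + B / n_bar
    if W == 0.0:
        R_hat = 1.0 if B == 0.0 else math.inf
    else:
        R_hat = V_hat / W
        if use_sqrt:
            R_hat = math.sqrt(R_hat)
    return TopoGRReport(
        W=W,
        B=B,
        V_hat=V_hat,
        R_hat=R_hat,
        rmsd=math.sqrt(V_hat),
        n_per_chain=Ns,
        m=m,
        top_size=None if top is None else len(top),
        metric=metric,
    )
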