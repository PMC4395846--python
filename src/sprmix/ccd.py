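"""Conditional clade distribution (CCD) estimation from a topology sample.

CCD approximates the posterior probability of a tree by a product of
conditional sister-clade probabilities given the parent clade, so that a
modest sample can assign probabilities to many never-sampled trees.  The
approximation assumes sister clades are conditionally independent given
their parent; when a posterior has correlated resolutions in different
parts of the tree (topological peaks), that assumption fails and CCD
systematically underestimates peak trees while overestimating the valley
trees between them.  The comparison helpers here expose exactly that.

Trees are unrooted, so clade extraction needs a consistent rooting: every
topology is rooted on the edge incident to a reference taxon (default: the
lexicographically smallest label), and clades are subsets of the remaining
"ingroup" leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import PosteriorSummary, Topology
from .spr import root_at_leaf

__all__ = ["CcdModel", "fit_ccd", "ccd_probability", "compare_ccd"]


@dataclass
class CcdModel:
    """Observed clade and child-pair counts under a fixed reference-taxon
    rooting.  For every parent clade the child-pair counts sum to the
    parent's count."""

    reference_taxon: str
    clade_counts: dict  # frozenset -> count
    pair_counts: dict  # frozenset -> {frozenset({child1, child2}) -> count}
    total: int
    leaves: frozenset

    def write_tsv(self, path) -> None:
        taxa = sorted(self.leaves - {self.reference_taxon})

        def mask(clade) -> str:
            return "".join("1" if t in clade else "0" for t in taxa)

        with open(path, "w") as fh:
            fh.write("parent\tchild1\tchild2\tcount\tparent_count\n")
            for parent in sorted(self.pair_counts, key=lambda c: (-len(c), mask(c))):
                for pair, cnt in sorted(
                    self.pair_counts[parent].items(),
                    key=lambda kv: sorted(mask(c) for c in kv[0]),
                ):
                    c1, c2 = sorted(pair, key=mask)
                    fh.write(
                        f"{mask(parent)}\t{mask(c1)}\t{mask(c2)}\t{cnt}\t"
                        f"{self.clade_counts[parent]}\n"
                    )


def _clade_decomposition(shape, out):
    """Yield (parent clade, child pair) for every internal node of a rooted
    shape; returns the leaf set below ``shape``."""
    if isinstance(shape, str):
        return frozenset((shape,))
    left = _clade_decomposition(shape[0], out)
    right = _clade_decomposition(shape[1], out)
    parent = left | right
    out.append((parent, frozenset((left, right))))
    return parent


def fit_ccd(summary: PosteriorSummary, reference_taxon: str | None = None) -> CcdModel:
    """Count clades and child pairs over the weighted topology sample."""
    if reference_taxon is None:
        reference_taxon = min(summary.leaves)
    if reference_taxon not in summary.leaves:
        raise ValueError(f"reference taxon {reference_taxon!r} absent from trees")
    clade_counts: dict = {}
    pair_counts: dict = {}
    for t, w in summary.counts.items():
        rooted = root_at_leaf(t, reference_taxon)
        ingroup_shape = (
            rooted.shape[1] if rooted.shape[0] == reference_taxon else rooted.shape[0]
        )
        decomp: list = []
        _clade_decomposition(ingroup_shape, decomp)
        for parent, pair in decomp:
            clade_counts[parent] = clade_counts.get(parent, 0) + w
            pair_counts.setdefault(parent, {})
            pair_counts[parent][pair] = pair_counts[parent].get(pair, 0) + w
    return CcdModel(
        reference_taxon=reference_taxon,
        clade_counts=clade_counts,
        pair_counts=pair_counts,
        total=summary.total,
        leaves=summary.leaves,
    )


def ccd_probability(
    model: CcdModel, topology: Topology, smoothing: float = 0.0
) -> float:
    """CCD probability of a topology: the product over its internal clades
    C (under the model's rooting) of P(children | C).

    Any unobserved parent clade or child pair gives probability 0 unless an
    add-``smoothing`` pseudo-count is requested (default off: estimates
    stay honest about the sample's support).
    """
    if topology.leaves != model.leaves:
        raise ValueError("leaf-set mismatch with fitted model")
    rooted = root_at_leaf(topology, model.reference_taxon)
    ingroup_shape = (
        rooted.shape[1] if rooted.shape[0] == model.reference_taxon else rooted.shape[0]
    )
    decomp: list = []
    _clade_decomposition(ingroup_shape, decomp)
    prob = 1.0
    for parent, pair in decomp:
        parent_count = model.clade_counts.get(parent, 0)
        pair_count = model.pair_counts.get(parent, {}).get(pair, 0)
        if smoothing:
            n_pairs = len(model.pair_counts.get(parent, {})) + 1
            prob *= (pair_count + smoothing) / (parent_count + smoothing * n_pairs)
        else:
            if pair_count == 0:
                return 0.0
            prob *= pair_count / parent_count
    return prob


def compare_ccd(
    model: CcdModel,
    summary: PosteriorSummary,
    top: list,
    clustering=None,
) -> pd.DataFrame:
    """Per-tree comparison of empirical posterior frequency with the CCD
    estimate (the Fig.-8-style table): frequency, CCD probability, their
    log10 values and ratio, plus a cluster label when a clustering is
    supplied."""
    import math

    rows = []
    assignment = clustering.assignment() if clustering is not None else {}
    for t in top:
        emp = summary.frequency(t)
        est = ccd_probability(model, t)
        rows.append(
            {
                "topology": t.newick,
                "frequency": emp,
                "ccd": est,
                "log10_frequency": math.log10(emp) if emp > 0 else float("-inf"),
                "log10_ccd": math.log10(est) if est > 0 else float("-inf"),
                "ratio": est / emp if emp > 0 else float("inf") if est > 0 else float("nan"),
                "cluster": assignment.get(t, -1),
            }
        )
    return pd.DataFrame(rows)
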