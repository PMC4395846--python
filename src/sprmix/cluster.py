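"""Descending-probability clustering for topological peak detection.

The procedure repeatedly takes the most probable unclustered topology as a
cluster center, computes the SPR distances from the center to every still
unclustered tree, sets the cluster radius to mu - sigma of those distances
(recomputed for each cluster), and absorbs every unclustered tree within
the radius.  It stops when all trees are clustered or after a maximum of 8
clusters.  A radius floor of 1 guards against sigma approaching or
exceeding mu, which would otherwise make every cluster a singleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import PosteriorSummary, Topology
from .spr import cached_spr_distance

__all__ = ["Cluster", "Clustering", "cluster_posterior"]


@dataclass
class Cluster:
    center: Topology
    radius: float
    members: list  # includes the center, in top-tree order
    probability: float


@dataclass
class Clustering:
    clusters: list
    unclustered: list

    def assignment(self) -> dict:
        out = {}
        for i, c in enumerate(self.clusters):
            for t in c.members:
                out[t] = i
        return out

    def label(self, t: Topology) -> int:
        return self.assignment().get(t, -1)


def _sd(values, population: bool) -> float:
    n = len(values)
    mean = sum(values) / n
    denom = n if population else max(n - 1, 1)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / denom)


def cluster_posterior(
    summary: PosteriorSummary,
    top: list,
    max_clusters: int = 8,
    radius_rule: str = "dynamic",
    fixed_radius: float | None = None,
    population_sd: bool = True,
    distance_mode: str = "leaf",
    radius_floor: float = 1.0,
) -> Clustering:
    """Iterative mu-sigma clustering of the top trees.

    The center's own (zero) distance does not enter mu or sigma: the radius
    is computed over the *remaining* unclustered trees only.  sigma is the
    population standard deviation by default (the distances are the whole
    population of unclustered trees); set ``population_sd=False`` for the
    n-1 convention.  ``radius_rule="fixed"`` uses ``fixed_radius`` instead,
    for posteriors where the dynamic rule picks poor radii.
    """
    if not top:
        raise ValueError("empty top-tree set")
    if radius_rule not in ("dynamic", "fixed"):
        raise ValueError(f"unknown radius_rule {radius_rule!r}")
    if radius_rule == "fixed" and fixed_radius is None:
        raise ValueError("fixed radius_rule needs fixed_radius")
    unclustered = list(top)  # already in descending-probability order
    clusters = []
    while unclustered and len(clusters) < max_clusters:
        center = unclustered.pop(0)
        dists = {
            t: cached_spr_distance(center, t, mode=distance_mode)
            for t in unclustered
        }
        if radius_rule == "fixed":
            radius = float(fixed_radius)
        elif not dists:
            radius = 0.0
        else:
            values = list(dists.values())
            mu = sum(values) / len(values)
            radius = max(radius_floor, mu - _sd(values, population_sd))
        members = [center] + [t for t in unclustered if dists[t] <= radius]
        unclustered = [t for t in unclustered if dists[t] > radius]
        clusters.append(
            Cluster(
                center=center,
                radius=radius,
                members=members,
                probability=sum(summary.frequency(t) for t in members),
            )
        )
    return Clustering(clusters=clusters, unclustered=unclustered)
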