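# Methods

This note records the models, estimators, numerical conventions and
design choices behind `sprmix`, and what the synthetic validation does
and does not demonstrate about real MCMC output.

## Topologies and canonical form

All analyses act on unrooted, binary, leaf-labeled tree topologies;
branch lengths and support values are discarded on ingestion, because
the object of study is the discrete state space traversed by topology
rearrangement moves.  Multifurcating input trees are rejected with an
error rather than auto-resolved: silently resolving a polytomy would
fabricate SPR distances that the data do not support.

Every topology is stored canonically: serialization is rooted at the
internal vertex adjacent to the lexicographically smallest leaf, and
children are ordered recursively by their smallest contained leaf.  Two
inputs describe the same unrooted topology exactly when their canonical
newick strings are equal, which gives O(1) identity tests, stable
hashing, and a deterministic total order used for tie-breaking.  The
invariance is exercised in tests by re-serializing trees under random
rootings, child orders and branch lengths.

Posterior summaries order distinct topologies by descending sample
count.  Ties are broken by first appearance in the concatenated traces;
under the default `auto` rule the tie-break switches to a seeded uniform
shuffle whenever any tie group exceeds 10 members, since
sample order is a biased ordering when nearly every sampled tree is
unique.  The m-capped credible set ("top trees") is the smallest head of
this ordering with cumulative probability above the level (default
0.95), returned whole if smaller than m = 4096 and truncated to m
otherwise.

Burn-in defaults to discarding the first 25% of samples.  MrBayes-style
Nexus `.t` files are read with their TRANSLATE tables honored.

## Exact SPR distances

The rooted SPR distance between two trees equals the number of edges cut
by a maximum agreement forest (MAF) of the two trees after each is
augmented with a formal root leaf (the augmentation prevents moves
through the root, without which the MAF identity fails).  The search is
a depth-first, k-bounded branch-and-reduce: cherries shared by both
trees are contracted and singleton components retired (both are safe
reductions); on an incompatible cherry (a, b) the search branches on
cutting a, cutting b, or — when a and b share a component — cutting
every subtree pendant on the a–b path; when they lie in different
components only the two cut branches apply.  Iterative deepening on k
returns the first feasible k, so the cost is exponential in the distance
but linear in tree size, and distance-1 decisions are near-instant.  On
success the surviving components form a certificate whose validity
(components partition the augmented leaf set; both trees restrict to the
same shape on every component; |components| − 1 = distance) is checked
in tests.

No MAF characterization exists for the unrooted SPR distance, so the
package reports the *best-rooting* distance: the minimum of the rooted
distance over root placements.  Two modes exist: `all` roots each tree
independently on every edge (O(edges²) rooted searches, wrapped in a
joint iterative deepening so cheap small-k rootings short-circuit), and
`leaf` roots both trees at the same leaf's pendant edge (O(n) searches,
an upper bound on `all`).  Both equal the true unrooted distance
whenever that distance is 1, which is the only fact graph construction
relies on; graphs use neighborhood hashing (enumerate each node's SPR
neighborhood once, look up canonical forms) rather than pairwise MAF
calls, and tests verify the two give identical edge sets.  Capped
computations return an explicit sentinel (`None`, written `NA`), never a
substituted number.

An independent brute-force BFS over SPR neighborhoods serves as the
oracle: best-rooting distances are checked against it exhaustively on
the 15-topology 5-taxon space and on hundreds of seeded 6–7-taxon pairs.
The known pathology — unrooted move sequences incompatible with any
single rooting — can make best-rooting exceed the true distance at
distances ≥ 2; no such case arises in the seeded test families, and the
tests assert best-rooting never falls *below* the oracle.

## Graphs, clustering, mixing, diagnostics

**SPR graphs.** Nodes are the top trees with posterior probability and
(best-rooting, `leaf` mode by default) SPR distance from the MAP tree;
edges are exactly the distance-1 pairs.  Connected components are
reported with their cumulative probability.  Exports (edge-list +
node-attribute TSV, GraphML) are deterministic, so export → import →
export round-trips byte-identically.

**Clustering.** The most probable unclustered tree seeds each cluster;
its radius is μ − σ of the SPR distances from the center to the
remaining unclustered trees, recomputed per cluster, stopping after 8
clusters.  Conventions the procedure's verbal description leaves open:
σ is the population standard deviation (the distances are the entire
population in play; a flag switches to n−1), the center's own zero
distance is excluded (the radius is computed over *unclustered* trees
only), and the radius is floored at 1 because a radius below 1 would
make every cluster a singleton whenever σ approaches μ.  A fixed-radius
mode exists for posteriors where the dynamic rule degenerates.

**Mixing statistics.** MAT(a→b) is the mean, over occurrences of a, of
the iterations until the next occurrence of b; occurrences with no
subsequent b are right-censored — dropped and counted, never reported as
zero.  MCT(j) = MAT(MAP→j) + MAT(j→MAP); the round-trip cover time
starts a window at every MAP occurrence (overlapping windows allowed, to
maximize observations) and ends at the first later MAP occurrence by
which every top tree has been seen.  All times are sample-step
differences multiplied by the sampling interval ι, i.e. reported in
iterations.  Each estimator has a linear implementation (prefix-sum
weighted means for MAT; a monotone two-pointer sweep for cover) proven
equal — exactly, including float identity — to its naive quadratic
definition on hundreds of random traces.  Weighted MCMC transition
graphs count successive-sample transitions between top trees (plus an
"other" sink), with self-transitions kept as dwell counts.

**ASDSF.** Split frequencies are computed per run over nontrivial
bipartitions (stored side-invariantly); splits exceeding a 10% frequency
in at least one run contribute the standard deviation of their per-run
frequencies, and ASDSF is the mean of these.  The cross-run SD uses the
sample (n−1) convention by default with a population-SD flag, and the
10% filter is applied to cumulative (whole-run) frequencies.  Max/RMS
split-frequency errors against a reference table are computed over the
union of splits.

**Topological PSRF.** With no mean defined for topologies, within- and
between-chain *variances* become mean square SPR (or RF) deviations:
s_i² = 1/(N_i(N_i−1)) Σ d², W = mean_i s_i², B sums d² over all ordered
chain pairs normalized by ((m−1)/m) Σ N_i N_j, V̂ = (1 − 1/n̄)W +
(1/n̄)B, R̂ = V̂/W.  Identical-topology comparisons are grouped — one
distance per distinct pair, weighted by count products — and
comparisons may be restricted to the top trees, in which case all
normalizers use the included counts N_i (the restricted and full forms
coincide when every sampled tree is a top tree).  Degenerate cases:
W = B = 0 reports R̂ = 1; W = 0 < B reports +∞.  R̂ is the plain ratio
as defined; a flag gives the classical √(V̂/W).  Note that because B is
a pairwise-distance sum rather than a variance of chain means, two
*identical* nonconstant chains give R̂ = 1 + (n−2)/n² — converging to 1
but not equal to it; √V̂ estimates the topology RMSD.

**CCD.** Trees are rooted on the pendant edge of a reference taxon
(default: smallest label; exposed because it affects estimates), and
each tree's probability is the product over its internal clades of
P(child pair | parent clade), with counts accumulated over the weighted
sample.  Unobserved parents or pairs give probability 0 by default (an
add-ε smoothing flag exists but stays off so comparisons with empirical
frequencies remain honest).  The distribution normalizes to 1 over all
assemblable trees, verified exhaustively on 5–6 ingroup taxa.  On
posteriors with correlated resolutions in different tree regions the
conditional-independence assumption fails in a quantifiable way: in the
minimal two-tree construction CCD assigns 0.25 to each sampled tree
(empirical 0.5) and 0.25 to each never-sampled recombination
(empirical 0).

## Synthetic targets and samplers

The generator emulates the defining feature of hard posteriors: k peak
centers at chosen pairwise SPR separations, per-peak weights, and
probability proportional to weight × λ^d within an SPR ball of fixed
radius around each center (d the distance to the nearest center; ties
and overlapping balls assign to the earlier peak and are flagged).  The
default study conditions are 8 taxa, two peaks at separation 4 with
weights 0.8/0.2, decay λ = 0.1, radius 1 — clouds of 91 trees whose peak
masses are exact when the balls are disjoint.  Centers are placed by a
steered outward walk (each step must increase the distance from the
origin by 1; unconstrained random walks collapse back), verified at the
exact separation with all-rootings distances.  An optional `bridge_mass`
spreads a small total mass over the interior of a shortest SPR path
between centers: with it the support is connected under 1-SPR proposals
(crossings happen but are rare — the valley mechanism), without it the
two clouds are genuinely disconnected, which is the cleanest setting for
testing component and cluster recovery from perfectly mixed samples.

Two samplers are provided.  `sample_iid` draws independently from the
target (the perfectly mixed reference).  `simulate_chain` runs
Metropolis–Hastings over topology space: `spr1` proposes a uniform SPR
neighbor; `spr-mix` adds, with probability p2, a uniform
neighbor-of-neighbor (a 2-step jump standing in for Metropolis-coupled
hot chains).  Acceptance uses exact proposal densities — neighborhood
sizes are computed, not assumed constant, and the 2-step density sums
over actual shared intermediates — so detailed balance holds exactly;
off-support proposals are rejected; disconnected supports are detected
and reported.  Stationarity, detailed-balance flow counts, and the
directional Metropolis-coupling effect (2-step jumps shrink minor-peak
commute times) are all asserted in tests.

What passing these tests shows — and does not.  The synthetic targets
have literal geometric decay, exactly known support, and no likelihood
model, alignment noise, branch lengths, or Metropolis-coupled
temperature ladders; chain lengths are desk-scale (10⁴–10⁵ steps on
~200-tree supports, chosen so the full suite runs in minutes).  Passing
therefore demonstrates that the estimators and graph machinery are
correct and that the qualitative phenomena (peaks as disconnected
components, inflated subpeak commute times, CCD valley bias, diagnostics
blind to unvisited peaks) follow from posterior shape alone; it does not
calibrate absolute iteration counts or error rates for any real data
set.

## Numerical conventions

- Capped distances return sentinels; censored time estimates report
  `None` with observation counts, never 0.
- Tie-breaking everywhere reduces to the canonical newick total order or
  to seeded RNGs; every public entry point with randomness takes a seed,
  and CLI manifests make reruns byte-identical (no timestamps).
- Grouped diagnostic sums accumulate integer-valued floats, so they
  equal the naive quadruple sums bit-for-bit at test scale.
- Radius μ − σ clustering floors at 1; empty unclustered remainders give
  a radius of 0 (singleton final cluster).
- The MAT "auto" tie rule threshold (10), ASDSF filter (0.10), credible
  level (0.95), m (4096), burn-in (0.25) and maximum cluster count (8)
  are the conventional defaults of the workflows this package supports;
  all are exposed as parameters.

## Known limitations

- Best-rooting SPR is an upper bound on the unrooted SPR distance for
  distances ≥ 2 (exact at ≤ 1); pathological rooting-incompatible cases,
  though never observed in the seeded families, are possible.
- The MAF search implements the standard three-way branching without the
  published engineering refinements (cluster reduction, strong bounds);
  it is built for the tens-of-taxa, small-distance regime of posterior
  analysis, not for hundreds of taxa at large distances.
- TBR *neighborhoods* are enumerated, but TBR distance is not computed.
- Rooted, dated (clock) trees are not first-class objects; chronogram
  posteriors must be treated as their unrooted shapes.
- The mixing estimators are empirical and censored; they do not solve
  for analytic access times of a known transition matrix.
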