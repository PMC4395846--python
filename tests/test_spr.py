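"""Exact SPR machinery: MAF distances vs the BFS oracle, neighborhoods,
RF distances, matrices and shortest paths."""

import itertools
import random

import pytest

import sprmix as sx
from sprmix.spr import (
    AgreementForest,
    ROOT_TOKEN,
    all_rootings,
    bfs_spr_distance,
    is_one_spr,
    neighbors,
    pairwise_matrix,
    rf_distance,
    root_at_leaf,
    rooted_spr_distance,
    spr_path,
    unrooted_spr_distance,
)
from sprmix.spr import _rnode


# --- test-local rooted-SPR oracle -----------------------------------------


def rooted_neighbors(shape):
    """All rooted shapes one rooted SPR move away (prune any proper
    subtree, regraft above any node of the remainder, including a new
    root).  Brute force; only for the oracle."""

    def prunings(n):
        if isinstance(n, str):
            yield n, None
            return
        a, b = n
        yield n, None
        for p, rem in prunings(a):
            yield p, (b if rem is None else _rnode(rem, b))
        for p, rem in prunings(b):
            yield p, (a if rem is None else _rnode(a, rem))

    def regrafts(n, pruned):
        yield _rnode(n, pruned)
        if not isinstance(n, str):
            a, b = n
            for v in regrafts(a, pruned):
                yield _rnode(v, b)
            for v in regrafts(b, pruned):
                yield _rnode(a, v)

    out = set()
    for pruned, remaining in prunings(shape):
        if remaining is None:
            continue
        for t in regrafts(remaining, pruned):
            out.add(t)
    out.discard(shape)
    return out


def rooted_bfs_distance(s1, s2, cap=8):
    if s1 == s2:
        return 0
    frontier, visited = {s1}, {s1}
    for depth in range(1, cap + 1):
        nxt = set()
        for s in frontier:
            for u in rooted_neighbors(s):
                if u == s2:
                    return depth
                if u not in visited:
                    visited.add(u)
                    nxt.add(u)
        frontier = nxt
    raise AssertionError("cap exceeded in rooted BFS oracle")


# --- rooted SPR -----------------------------------------------------------


class TestRootedSpr:
    def test_identity(self):
        r = all_rootings(sx.random_topology(6, seed=1))[0]
        assert rooted_spr_distance(r, r) == 0

    def test_one_move_by_construction(self, rng):
        for _ in range(10):
            t = sx.random_topology(6, seed=rng.randrange(2**31))
            r1 = all_rootings(t)[0]
            moved = rng.choice(sorted(rooted_neighbors(r1.shape), key=repr))
            r2 = sx.RootedTopology.from_shape(moved)
            assert rooted_spr_distance(r1, r2) == 1

    def test_caterpillar_reversal_matches_rooted_bfs(self):
        # rooted caterpillars: unrooted they are the same topology, rooted
        # they are far apart
        def caterpillar(leaves):
            shape = leaves[0]
            for leaf in leaves[1:]:
                shape = _rnode(shape, leaf)
            return sx.RootedTopology.from_shape(shape)

        r1 = caterpillar(list("abcdef"))
        r2 = caterpillar(list("fedcba"))
        d = rooted_spr_distance(r1, r2)
        assert d == rooted_bfs_distance(r1.shape, r2.shape)

    def test_cap_returns_sentinel_not_a_number(self):
        t1 = sx.random_topology(7, seed=11)
        t2 = sx.random_topology(7, seed=99)
        r1, r2 = all_rootings(t1)[0], all_rootings(t2)[0]
        full = rooted_spr_distance(r1, r2)
        if full > 1:
            assert rooted_spr_distance(r1, r2, cap=full - 1) is None

    def test_leaf_set_mismatch(self):
        r1 = all_rootings(sx.random_topology(5, seed=1))[0]
        r2 = all_rootings(sx.random_topology(6, seed=1))[0]
        with pytest.raises(ValueError):
            rooted_spr_distance(r1, r2)


class TestAgreementForestCertificate:
    def _restrict(self, shape, keep):
        if isinstance(shape, str):
            return shape if shape in keep else None
        kids = [k for k in (self._restrict(c, keep) for c in shape) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _rnode(kids[0], kids[1])

    @pytest.mark.parametrize("seed", [2, 3, 5, 8])
    def test_components_agree_in_both_trees(self, seed):
        rng = random.Random(seed)
        t1 = sx.random_topology(7, seed=seed)
        t2 = t1
        for _ in range(rng.randint(1, 3)):
            t2 = sx.synthetic.random_spr_move(t2, rng)
        r1, r2 = root_at_leaf(t1, min(t1.leaves)), root_at_leaf(t2, min(t2.leaves))
        d, forest = rooted_spr_distance(r1, r2, certificate=True)
        assert isinstance(forest, AgreementForest)
        assert len(forest.components) - 1 == forest.n_cuts == d
        # components partition the augmented leaf set
        union = frozenset().union(*forest.components)
        assert union == t1.leaves | {ROOT_TOKEN}
        assert sum(len(c) for c in forest.components) == len(union)
        # restricting both trees to each component yields the same shape
        a1 = (r1.shape, ROOT_TOKEN)
        a2 = (r2.shape, ROOT_TOKEN)
        for comp in forest.components:
            assert self._restrict(a1, comp) == self._restrict(a2, comp)


# --- unrooted best-rooting vs BFS oracle ----------------------------------


class TestUnrootedSpr:
    def test_exhaustive_five_taxon_oracle_equivalence(self, five_taxon_topologies):
        for t1, t2 in itertools.combinations(five_taxon_topologies, 2):
            b = bfs_spr_distance(t1, t2, cap=4)
            assert unrooted_spr_distance(t1, t2, mode="all") == b
            assert unrooted_spr_distance(t1, t2, mode="leaf") >= b

    def test_single_move_pairs_are_distance_one(self, rng):
        for _ in range(20):
            t = sx.random_topology(rng.randint(5, 9), seed=rng.randrange(2**31))
            u = sx.synthetic.random_spr_move(t, rng)
            assert unrooted_spr_distance(t, u, mode="all") == 1
            assert unrooted_spr_distance(t, u, mode="leaf") == 1

    def test_leaf_mode_never_below_all_mode(self, rng):
        for _ in range(15):
            t1 = sx.random_topology(6, seed=rng.randrange(2**31))
            t2 = sx.random_topology(6, seed=rng.randrange(2**31))
            a = unrooted_spr_distance(t1, t2, mode="all", cap=3)
            l = unrooted_spr_distance(t1, t2, mode="leaf", cap=3)
            if a is None:
                assert l is None
            else:
                assert l is None or l >= a

    def test_identity_and_mismatch(self):
        t = sx.random_topology(6, seed=4)
        assert unrooted_spr_distance(t, t) == 0
        with pytest.raises(ValueError):
            unrooted_spr_distance(t, sx.random_topology(7, seed=4))


class TestIsOneSpr:
    def test_self_is_not_distance_one(self, five_taxon_topologies):
        t = five_taxon_topologies[0]
        assert not is_one_spr(t, t)

    def test_matches_bfs_on_all_five_taxon_pairs(self, five_taxon_topologies):
        for t1 in five_taxon_topologies:
            for t2 in five_taxon_topologies:
                expected = t1 != t2 and bfs_spr_distance(t1, t2, cap=1) == 1
                assert is_one_spr(t1, t2) == expected

    def test_every_neighbor_is_distance_one(self, rng):
        t = sx.random_topology(6, seed=9)
        for u in neighbors(t, "spr"):
            assert is_one_spr(t, u)


# --- neighborhoods --------------------------------------------------------


class TestNeighborhoods:
    def test_four_taxon_spr_neighbors_are_the_other_two(self, four_taxon_topologies):
        for t in four_taxon_topologies:
            nbrs = neighbors(t, "spr")
            assert nbrs == set(four_taxon_topologies) - {t}

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_nni_neighborhood_size(self, n):
        t = sx.random_topology(n, seed=n)
        assert len(neighbors(t, "nni")) == 2 * (n - 3)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_containment_nni_spr_tbr(self, n):
        t = sx.random_topology(n, seed=100 + n)
        nni, spr, tbr = (neighbors(t, m) for m in ("nni", "spr", "tbr"))
        assert nni <= spr <= tbr

    def test_spr_neighbors_at_bfs_distance_one(self):
        t = sx.random_topology(6, seed=17)
        assert all(bfs_spr_distance(t, u, cap=1) == 1 for u in neighbors(t, "spr"))

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            sx.random_topology(3, seed=0)


# --- BFS oracle properties ------------------------------------------------


class TestBfsOracle:
    def test_identity_and_neighbor(self):
        t = sx.random_topology(6, seed=2)
        u = next(iter(neighbors(t, "spr")))
        assert bfs_spr_distance(t, t) == 0
        assert bfs_spr_distance(t, u) == 1

    def test_symmetry(self, rng):
        for _ in range(50):
            t1 = sx.random_topology(6, seed=rng.randrange(2**31))
            t2 = sx.random_topology(6, seed=rng.randrange(2**31))
            assert bfs_spr_distance(t1, t2, cap=4) == bfs_spr_distance(t2, t1, cap=4)

    def test_triangle_inequality(self, rng):
        for _ in range(100):
            a, b, c = (
                sx.random_topology(6, seed=rng.randrange(2**31)) for _ in range(3)
            )
            dab = bfs_spr_distance(a, b, cap=5)
            dbc = bfs_spr_distance(b, c, cap=5)
            dac = bfs_spr_distance(a, c, cap=5)
            assert dac <= dab + dbc


# --- RF -------------------------------------------------------------------


class TestRfDistance:
    def test_identity_and_nni(self):
        t = sx.random_topology(7, seed=5)
        assert rf_distance(t, t) == 0
        for u in neighbors(t, "nni"):
            assert rf_distance(t, u) == 2  # one split replaced on each side

    @pytest.mark.parametrize("n", [5, 6])
    def test_maximum_over_exhaustive_pairs(self, n):
        tops = sx.enumerate_topologies([chr(97 + i) for i in range(n)])
        maxrf = max(
            rf_distance(t1, t2) for t1, t2 in itertools.combinations(tops, 2)
        )
        assert maxrf == 2 * (n - 3)

    def test_agrees_with_dendropy(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        tns = dendropy.TaxonNamespace()
        for _ in range(20):
            t1 = sx.random_topology(8, seed=rng.randrange(2**31))
            t2 = sx.random_topology(8, seed=rng.randrange(2**31))
            d1 = dendropy.Tree.get(data=t1.newick, schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.newick, schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert rf_distance(t1, t2) == treecompare.symmetric_difference(d1, d2)

    def test_single_spr_pair_with_large_rf(self):
        # moving a subtree along a caterpillar changes many splits at once
        t = sx.Topology.from_newick("(((((((a,b),c),d),e),f),g),h);")
        best = max(rf_distance(t, u) for u in neighbors(t, "spr"))
        assert best >= 4


# --- matrices and paths ---------------------------------------------------


class TestPairwiseMatrix:
    def test_identical_trees(self):
        t = sx.random_topology(5, seed=3)
        m = pairwise_matrix([t, t], metric="spr")
        assert m.matrix == [[0, 0], [0, 0]]

    def test_four_taxon_triangle(self, four_taxon_topologies):
        m = pairwise_matrix(four_taxon_topologies, metric="spr")
        for i in range(3):
            for j in range(3):
                assert m.matrix[i][j] == (0 if i == j else 1)

    def test_symmetry_and_cap_sentinel(self, rng, tmp_path):
        trees = [sx.random_topology(6, seed=s) for s in (1, 2, 3, 4)]
        m = pairwise_matrix(trees, metric="spr", cap=1)
        for i in range(4):
            for j in range(4):
                assert m.matrix[i][j] == m.matrix[j][i]
        # capped entries are written as NA, never fabricated
        path = tmp_path / "mat.tsv"
        m.write_tsv(path)
        body = path.read_text()
        if any(None in row for row in m.matrix):
            assert "NA" in body

    def test_cap1_equals_maf_distance_one_test(self, rng):
        trees = [sx.random_topology(6, seed=s) for s in range(6)]
        hashed = pairwise_matrix(trees, metric="spr", cap=1)
        for i in range(len(trees)):
            for j in range(i + 1, len(trees)):
                exact = unrooted_spr_distance(trees[i], trees[j], mode="all", cap=1)
                assert hashed.matrix[i][j] == exact


class TestSprPath:
    def test_trivial_paths(self):
        t = sx.random_topology(6, seed=8)
        u = next(iter(neighbors(t, "spr")))
        assert spr_path(t, t) == [t]
        assert spr_path(t, u) == [t, u]

    def test_distance_two_path_middle_is_shared_neighbor(self, rng):
        while True:
            t = sx.random_topology(6, seed=rng.randrange(2**31))
            u = sx.random_topology(6, seed=rng.randrange(2**31))
            if bfs_spr_distance(t, u, cap=2) == 2:
                break
        path = spr_path(t, u, cap=2)
        assert len(path) == 3
        assert is_one_spr(path[0], path[1]) and is_one_spr(path[1], path[2])

    def test_cap_exceeded_raises(self):
        t = sx.Topology.from_newick("(((((((a,b),c),d),e),f),g),h);")
        far = sx.Topology.from_newick("(((((((h,g),f),e),d),c),b),a);")
        if bfs_spr_distance(t, far, cap=1) is None:
            with pytest.raises(ValueError):
                spr_path(t, far, cap=1)
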