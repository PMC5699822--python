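import itertools

import dendropy
import numpy as np
import pytest

from corepart import (
    pairwise_distance_table,
    path_distance,
    rf_distance,
    simulate_tree,
    spr_distance_approx,
    spr_distance_exact,
)
from corepart.treedist import UnrootedTree, spr_neighbors


def all_topologies(leaves):
    """Every unrooted binary topology on the leaf set, by stepwise leaf
    addition (independent enumeration used as the exhaustive suite)."""
    first3, rest = leaves[:3], leaves[3:]
    base = UnrootedTree.from_newick(f"({first3[0]},{first3[1]},{first3[2]});")
    trees = [base]
    for leaf in rest:
        grown = []
        for t in trees:
            for u, v in t.edges():
                new = t.copy()
                w = next(new._counter)
                new.adj[u].discard(v)
                new.adj[v].discard(u)
                new.adj[w] = {u, v, leaf}
                new.adj[u].add(w)
                new.adj[v].add(w)
                new.adj[leaf] = {w}
                grown.append(new)
        trees = grown
    return trees


def random_spr_walk(tree, k, seed):
    rng = np.random.default_rng(seed)
    current = tree
    for _ in range(k):
        nbrs = spr_neighbors(current)
        current = nbrs[rng.integers(len(nbrs))]
    return current


class TestRobinsonFoulds:
    def test_identical_trees(self):
        assert rf_distance("((a,b),(c,d));", "((a,b),(c,d));") == 0

    def test_four_taxon_swap(self):
        assert rf_distance("((a,b),(c,d));", "((a,c),(b,d));") == 2

    def test_caterpillar_mirror_is_same_unrooted_topology(self):
        cat = "(((((a,b),c),d),e),f);"
        mirror = "(((((f,e),d),c),b),a);"
        assert rf_distance(cat, mirror) == 0

    def test_matches_dendropy_on_random_trees(self):
        ns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        rng = np.random.default_rng(3)
        for rep in range(20):
            newicks = [
                simulate_tree(8, int(rng.integers(1 << 30)), 0.2).as_string(schema="newick")
                for _ in range(2)
            ]
            t1, t2 = (
                dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
                for nwk in newicks
            )
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
            assert rf_distance(newicks[0], newicks[1]) == expected

    def test_disjoint_leafsets_rejected(self):
        with pytest.raises(ValueError, match="no leaves"):
            rf_distance("((a,b),(c,d));", "((w,x),(y,z));")

    def test_restrict_to_shared_prunes(self, caplog):
        t1 = "(((a,b),(c,d)),e);"
        t2 = "((a,b),(c,d));"
        with pytest.raises(ValueError):
            rf_distance(t1, t2)
        with caplog.at_level("WARNING"):
            assert rf_distance(t1, t2, restrict_to_shared=True) == 0
        assert "shared leaves" in caplog.text

    def test_multifurcations_supported(self):
        assert rf_distance("((a,b),c,d,e);", "((a,b),(c,d),e);") == 1

    def test_triangle_inequality_on_six_leaf_suite(self):
        trees = all_topologies(list("abcdef"))
        rng = np.random.default_rng(1)
        idx = rng.integers(0, len(trees), size=(60, 3))
        for i, j, k in idx:
            dij = len(trees[i].splits() ^ trees[j].splits())
            djk = len(trees[j].splits() ^ trees[k].splits())
            dik = len(trees[i].splits() ^ trees[k].splits())
            assert dik <= dij + djk


class TestPathDistance:
    def test_identical_trees(self):
        assert path_distance("((a,b),(c,d));", "((a,b),(c,d));") == 0.0

    def test_four_taxon_example(self):
        # four of the six leaf pairs change their path length by one
        assert path_distance("((a,b),(c,d));", "((a,c),(b,d));") == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            t1 = simulate_tree(7, int(rng.integers(1 << 30))).as_string(schema="newick")
            t2 = simulate_tree(7, int(rng.integers(1 << 30))).as_string(schema="newick")
            assert path_distance(t1, t2) == pytest.approx(path_distance(t2, t1))

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(ValueError):
            path_distance("((a,b),(c,d));", "((a,b),(c,e));")


class TestSprExact:
    def test_identical_trees(self):
        assert spr_distance_exact("((a,b),(c,d),e);", "((a,b),(c,d),e);") == 0

    def test_neighbor_count_matches_closed_form(self):
        # unrooted binary n-leaf trees have 2(n-3)(2n-7) SPR neighbors
        for n in (5, 6, 7):
            tree = UnrootedTree.from_dendropy(simulate_tree(n, 1))
            distinct = {t.key() for t in spr_neighbors(tree)} - {tree.key()}
            assert len(distinct) == 2 * (n - 3) * (2 * n - 7)

    def test_single_moves_have_distance_one(self):
        for seed in range(5):
            base = UnrootedTree.from_dendropy(simulate_tree(7, 40 + seed))
            moved = random_spr_walk(base, 1, seed)
            if moved.key() == base.key():
                continue
            assert spr_distance_exact(base, moved) == 1

    def test_two_move_pairs_within_two(self):
        for seed in range(5):
            base = UnrootedTree.from_dendropy(simulate_tree(6, 60 + seed))
            moved = random_spr_walk(base, 2, seed)
            d = spr_distance_exact(base, moved)
            assert d is not None and d <= 2

    def test_symmetry(self):
        for seed in range(3):
            base = UnrootedTree.from_dendropy(simulate_tree(6, 80 + seed))
            moved = random_spr_walk(base, 2, seed)
            assert spr_distance_exact(base, moved) == spr_distance_exact(moved, base)

    def test_exceeding_max_depth_returns_none(self):
        cat = "(((((a,b),c),d),e),f);"
        far = "(((((a,f),d),b),e),c);"
        assert spr_distance_exact(cat, far, max_d=0) is None

    def test_too_many_leaves_rejected(self):
        t = simulate_tree(12, 1)
        with pytest.raises(ValueError, match="10"):
            spr_distance_exact(t, t)


class TestSprApprox:
    def test_identical_trees(self):
        assert spr_distance_approx("((a,b),(c,d),e);", "((a,b),(c,d),e);") == 0

    def test_zero_iff_identical(self):
        base = UnrootedTree.from_dendropy(simulate_tree(7, 2))
        moved = random_spr_walk(base, 1, 9)
        if moved.key() != base.key():
            assert spr_distance_approx(base, moved) >= 1

    def test_matches_exact_on_single_spr_pairs(self):
        hits = 0
        for seed in range(8):
            base = UnrootedTree.from_dendropy(simulate_tree(9, 100 + seed))
            moved = random_spr_walk(base, 1, seed)
            if moved.key() == base.key():
                continue
            hits += 1
            assert spr_distance_approx(base, moved) == 1
        assert hits >= 5

    def test_never_undercuts_exact(self):
        for seed in range(10):
            base = UnrootedTree.from_dendropy(simulate_tree(8, 200 + seed))
            moved = random_spr_walk(base, int(1 + seed % 3), seed)
            exact = spr_distance_exact(base, moved, max_d=3)
            approx = spr_distance_approx(base, moved)
            if exact is None:
                assert approx > 3
            else:
                assert approx >= exact

    def test_upper_bounded_by_move_count(self):
        for seed in range(6):
            base = UnrootedTree.from_dendropy(simulate_tree(8, 300 + seed))
            k = 1 + seed % 3
            moved = random_spr_walk(base, k, seed)
            assert spr_distance_approx(base, moved) <= k


class TestPairwiseTable:
    def test_identical_pair_all_zero(self):
        trees = {
            "m1": "((a,b),(c,d),e);",
            "m2": "((a,b),(c,d),e);",
        }
        tables = pairwise_distance_table(trees)
        assert set(tables) == {"rf", "path", "spr"}
        for table in tables.values():
            assert table.loc["m2", "m1"] in ("0", "0.0")

    def test_lower_triangle_layout(self):
        trees = {
            "x": "((a,b),(c,d),e);",
            "y": "((a,c),(b,d),e);",
            "z": "((a,d),(b,c),e);",
        }
        tables = pairwise_distance_table(trees)
        rf = tables["rf"]
        assert rf.loc["x", "x"] == "-"
        assert rf.loc["x", "y"] == ""          # upper triangle empty
        assert rf.loc["y", "x"] == str(rf_distance(trees["y"], trees["x"]))

    def test_entries_match_individual_calls(self):
        trees = {f"m{i}": simulate_tree(6, 500 + i).as_string(schema="newick") for i in range(3)}
        tables = pairwise_distance_table(trees)
        names = list(trees)
        for i, ni in enumerate(names):
            for j in range(i):
                assert tables["path"].loc[ni, names[j]] == (
                    f"{path_distance(trees[ni], trees[names[j]]):.1f}"
                )
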