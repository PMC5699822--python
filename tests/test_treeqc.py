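import math

import dendropy
import numpy as np
import pytest

from corepart import (
    LocusAlignment,
    LocusQCRecord,
    SplitFrequencyTable,
    TreeSample,
    apply_burnin,
    asdsf,
    filter_low_support_loci,
    flag_saturated_loci,
    mcct,
    mean_support,
    nj_guide_tree,
    p_distance_matrix,
    patristic_matrix,
    rf_distance,
    saturation_regression,
    simulate_locus,
    simulate_posterior_sample,
    simulate_tree,
    split_frequencies,
)
from corepart.treeqc import nontrivial_splits, read_tree, read_tree_sample

from conftest import flat_config


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestMeanSupport:
    def test_two_internal_edges(self):
        t = tree_of("((a,b)100,((c,d)50,e));")
        assert mean_support(t) == pytest.approx(75.0)

    def test_posterior_scale_autodetected(self):
        t = tree_of("((a,b)0.9,((c,d)0.5,e));")
        assert mean_support(t) == pytest.approx(70.0)

    def test_star_tree_rejected(self):
        with pytest.raises(ValueError):
            mean_support(tree_of("(a,b,c,d);"))

    def test_constant_supports(self):
        t = tree_of("((a,b)88,((c,d)88,e));")
        assert mean_support(t) == pytest.approx(88.0)


class TestSupportFilter:
    def test_bottom_decile_dropped(self):
        records = [LocusQCRecord(f"l{i}", mean_support=float(i)) for i in range(1, 11)]
        filter_low_support_loci(records, q=0.10)
        # type-7 quantile of 1..10 at q=0.1 is 1.9
        dropped = [r.locus_id for r in records if r.dropped_low_support]
        assert dropped == ["l1"]

    def test_equal_supports_keep_everything(self):
        records = [LocusQCRecord(f"l{i}", mean_support=80.0) for i in range(5)]
        filter_low_support_loci(records, q=0.10)
        assert not any(r.dropped_low_support for r in records)

    def test_zero_quantile_keeps_everything(self):
        records = [LocusQCRecord(f"l{i}", mean_support=float(i)) for i in range(5)]
        filter_low_support_loci(records, q=0.0)
        assert not any(r.dropped_low_support for r in records)

    def test_drop_rate_tracks_quantile(self):
        rng = np.random.default_rng(0)
        records = [
            LocusQCRecord(f"l{i}", mean_support=float(s))
            for i, s in enumerate(rng.uniform(40, 100, 400))
        ]
        filter_low_support_loci(records, q=0.10)
        n_dropped = sum(r.dropped_low_support for r in records)
        assert abs(n_dropped - 40) <= 1


class TestDistances:
    def test_p_distance_example(self):
        aln = LocusAlignment("x", ["a", "b"], ["ACGT", "AGGT"])
        assert p_distance_matrix(aln)[0, 1] == pytest.approx(0.25)

    def test_identical_sequences(self):
        aln = LocusAlignment("x", ["a", "b"], ["ACGT", "ACGT"])
        assert p_distance_matrix(aln)[0, 1] == 0.0

    def test_no_overlap_is_missing(self, caplog):
        aln = LocusAlignment("x", ["a", "b", "c"], ["A---", "-AAA", "AAAA"])
        with caplog.at_level("WARNING"):
            mat = p_distance_matrix(aln)
        assert np.isnan(mat[0, 1])
        assert "overlap" in caplog.text

    def test_patristic_path_sums(self):
        mat = patristic_matrix(
            tree_of("((a:1,b:2):1,(c:1,d:1):0);"), ["a", "b", "c", "d"]
        )
        assert mat[0, 1] == pytest.approx(3.0)  # a-b
        assert mat[0, 2] == pytest.approx(3.0)  # a-c
        assert np.allclose(mat, mat.T) and np.all(np.diag(mat) == 0)

    def test_zero_length_tree(self):
        mat = patristic_matrix(tree_of("((a:0,b:0):0,(c:0,d:0):0);"))
        assert np.all(mat == 0)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            patristic_matrix(tree_of("((a,b),(c,d));"))


class TestSaturation:
    def test_exact_linear_relation(self):
        patristic = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        slope, intercept, r2 = saturation_regression(0.5 * patristic, patristic)
        assert (slope, intercept, r2) == pytest.approx((0.5, 0.0, 1.0))

    def test_constant_response(self):
        patristic = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        p = np.full_like(patristic, 0.3)
        slope, _, _ = saturation_regression(p, patristic)
        assert slope == pytest.approx(0.0)

    def test_saturated_locus_has_depressed_slope(self, yule_tree):
        cfg = flat_config(n_taxa=6, locus_length_range=(500, 500), tree_height=0.2)
        slopes = {}
        for scale in (1.0, 10.0):
            aln, _ = simulate_locus(yule_tree, cfg, branch_scale=scale, seed=13)
            njt = nj_guide_tree(aln)
            slopes[scale], _, _ = saturation_regression(
                p_distance_matrix(aln), patristic_matrix(njt, aln.taxa)
            )
        assert slopes[10.0] < slopes[1.0]

    def test_tukey_fence_flags_outlier(self):
        records = [LocusQCRecord(f"n{i}", sat_slope=0.9) for i in range(19)]
        records.append(LocusQCRecord("sat", sat_slope=0.2))
        flag_saturated_loci(records)
        flagged = [r.locus_id for r in records if r.dropped_saturated]
        assert flagged == ["sat"]

    def test_identical_slopes_not_flagged(self):
        records = [LocusQCRecord(f"n{i}", sat_slope=0.8) for i in range(6)]
        flag_saturated_loci(records)
        assert not any(r.dropped_saturated for r in records)

    def test_too_few_records_rejected(self):
        records = [LocusQCRecord(f"n{i}", sat_slope=0.8) for i in range(3)]
        with pytest.raises(ValueError):
            flag_saturated_loci(records)


class TestBurnin:
    def _sample(self, n, burnin):
        trees = [tree_of("((a,b),(c,d));") for _ in range(n)]
        return TreeSample(trees, burnin_fraction=burnin)

    def test_quarter_burnin(self):
        out = apply_burnin(self._sample(10000, 0.25))
        assert len(out) == 7500
        # two such runs combined leave 15000 post-burn-in samples
        assert 2 * len(out) == 15000

    def test_zero_burnin_unchanged(self):
        assert len(apply_burnin(self._sample(8, 0.0))) == 8

    def test_half_of_four(self):
        sample = self._sample(4, 0.5)
        out = apply_burnin(sample)
        assert out.trees == sample.trees[2:]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            apply_burnin(TreeSample([], burnin_fraction=0.25))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            apply_burnin(self._sample(4, 1.0))


class TestSplitFrequencies:
    def test_single_topology_run(self):
        run = TreeSample([tree_of("((a,b),(c,d),e);")] * 5)
        table = split_frequencies([run, run])
        assert all(np.allclose(row, 1.0) for row in table.frequencies.values())

    def test_hand_counted_toy_sample(self):
        t1 = "((a,b),(c,d),e);"
        t2 = "((a,c),(b,d),e);"
        run1 = TreeSample([tree_of(t1), tree_of(t1), tree_of(t2)])
        run2 = TreeSample([tree_of(t2), tree_of(t2), tree_of(t2)])
        table = split_frequencies([run1, run2])
        # the {c,d} split (canonical side, excluding 'a') appears in 2 of 3
        # trees of run 1 and never in run 2
        assert np.allclose(table.frequencies[frozenset(["c", "d"])], [2 / 3, 0.0])
        # the {b,d} split appears in 1 of 3 trees of run 1 and all of run 2
        assert np.allclose(table.frequencies[frozenset(["b", "d"])], [1 / 3, 1.0])

    def test_mismatched_leafsets_rejected(self):
        run1 = TreeSample([tree_of("((a,b),(c,d));")])
        run2 = TreeSample([tree_of("((a,b),(c,e));")])
        with pytest.raises(ValueError, match="leaf"):
            split_frequencies([run1, run2])


class TestAsdsf:
    def test_identical_runs_are_converged(self):
        run = TreeSample([tree_of("((a,b),(c,d),e);")] * 10)
        assert asdsf(split_frequencies([run, run])) == 0.0

    def test_worked_example(self):
        table = SplitFrequencyTable(
            {frozenset(["c", "d"]): np.array([0.8, 0.6])}, n_runs=2
        )
        assert asdsf(table) == pytest.approx(math.sqrt(0.02), abs=1e-12)
        assert asdsf(table) == pytest.approx(0.1414, abs=1e-4)

    def test_rare_splits_excluded(self):
        table = SplitFrequencyTable(
            {
                frozenset(["c", "d"]): np.array([0.9, 0.9]),
                frozenset(["b", "d"]): np.array([0.05, 0.08]),
            },
            n_runs=2,
        )
        assert asdsf(table) == 0.0  # only the converged split qualifies

    def test_single_run_rejected(self):
        table = SplitFrequencyTable({frozenset(["c", "d"]): np.array([0.9])}, n_runs=1)
        with pytest.raises(ValueError):
            asdsf(table)


class TestMcct:
    def test_majority_topology_wins(self):
        ns = dendropy.TaxonNamespace()
        t1 = "((a,b),(c,d),e);"
        t2 = "((a,c),(b,d),e);"
        trees = [
            dendropy.Tree.get(data=s, schema="newick", taxon_namespace=ns)
            for s in (t1, t1, t1, t2)
        ]
        winner = mcct(TreeSample(trees))
        assert rf_distance(winner, trees[0]) == 0

    def test_identical_sample_full_support(self):
        run = TreeSample([tree_of("((a,b),(c,d),e);")] * 4)
        winner = mcct(run)
        posteriors = [
            float(n.label) for n in winner.preorder_internal_node_iter()
        ]
        assert posteriors and all(p == 1.0 for p in posteriors)

    def test_matches_exhaustive_scoring(self):
        truth = simulate_tree(5, 31, 0.2)
        sample = simulate_posterior_sample(truth, 20, perturbation=0.8, seed=5)
        winner = mcct(sample)
        # independent oracle: score every sampled tree directly
        from corepart.treeqc import _clade_leafsets

        n = len(sample.trees)
        counts = {}
        tree_clades = []
        for t in sample.trees:
            clades = {c for c in _clade_leafsets(t).values() if len(c) >= 2}
            tree_clades.append(clades)
            for c in clades:
                counts[c] = counts.get(c, 0) + 1
        scores = [
            sum(math.log(counts[c] / n) for c in clades) for clades in tree_clades
        ]
        best = max(range(n), key=lambda i: scores[i])
        assert rf_distance(winner, sample.trees[best]) == 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mcct(TreeSample([]))


class TestTreeIO:
    def test_read_tree_sample_with_prefixes(self, tmp_path):
        path = tmp_path / "run1.t"
        path.write_text(
            "#NEXUS-ish header\n"
            "tree rep.1 = ((a:1,b:1):1,(c:1,d:1):1);\n"
            "tree rep.2 = ((a:1,c:1):1,(b:1,d:1):1);\n"
        )
        sample = read_tree_sample(path)
        assert len(sample) == 2
        assert {l.taxon.label for l in sample.trees[0].leaf_node_iter()} == set("abcd")
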