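import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corepart import (
    LocusAlignment,
    MatrixFilterConfig,
    count_informative_sites,
    drop_empty_columns,
    filter_by_completeness,
    read_locus_alignments,
    summarize_loci,
    write_concatenated_matrix,
)
from corepart.alignments import (
    DuplicateTaxonError,
    RaggedAlignmentError,
    read_concatenated_matrix,
)

from conftest import write_fasta


class TestReadLocusAlignments:
    def test_reads_one_alignment_per_fasta(self, tmp_path):
        for i in range(3):
            write_fasta(
                tmp_path / f"uce-{i}.fasta",
                LocusAlignment(f"uce-{i}", ["a", "b"], ["ACGT", "ACGA"]),
            )
        alns = read_locus_alignments(tmp_path)
        assert [a.locus_id for a in alns] == ["uce-0", "uce-1", "uce-2"]
        assert all(a.length == 4 for a in alns)

    def test_sequences_uppercased(self, tmp_path):
        (tmp_path / "x.fasta").write_text(">a\nacgt\n>b\nac-t\n")
        (aln,) = read_locus_alignments(tmp_path)
        assert aln.seqs == ["ACGT", "AC-T"]

    def test_ragged_alignment_names_locus(self, tmp_path):
        (tmp_path / "bad-locus.fasta").write_text(">a\n" + "A" * 100 + "\n>b\n" + "A" * 98 + "\n")
        with pytest.raises(RaggedAlignmentError, match="bad-locus"):
            read_locus_alignments(tmp_path)

    def test_duplicate_taxon_rejected(self, tmp_path):
        (tmp_path / "dup.fasta").write_text(">a\nACGT\n>a\nACGA\n")
        with pytest.raises(DuplicateTaxonError, match="dup"):
            read_locus_alignments(tmp_path)

    def test_empty_directory_warns(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            assert read_locus_alignments(tmp_path) == []
        assert "no FASTA" in caplog.text


class TestDropEmptyColumns:
    def test_all_missing_columns_removed(self):
        aln = LocusAlignment("x", ["a", "b", "c"], ["A-C", "A-N", "A-C"])
        out = drop_empty_columns(aln)
        # column 2 has real states in two taxa, so only column 1 goes
        assert out.seqs == ["AC", "AN", "AC"]

    def test_mixed_missing_symbols_count_as_empty(self):
        aln = LocusAlignment("x", ["a", "b", "c"], ["A-", "An", "A?"])
        assert drop_empty_columns(aln).seqs == ["A", "A", "A"]

    def test_clean_alignment_unchanged(self, small_alignment):
        assert drop_empty_columns(small_alignment) is small_alignment

    def test_fully_missing_alignment_rejected(self):
        aln = LocusAlignment("x", ["a", "b"], ["--", "NN"])
        with pytest.raises(ValueError, match="x"):
            drop_empty_columns(aln)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT-N?", min_size=6, max_size=6), min_size=2, max_size=5))
    def test_idempotent(self, rows):
        aln = LocusAlignment("h", [f"t{i}" for i in range(len(rows))], rows)
        try:
            once = drop_empty_columns(aln)
        except ValueError:
            return
        twice = drop_empty_columns(once)
        assert twice.seqs == once.seqs


class TestInformativeSites:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            (["ACGA", "ACGA", "GCTA", "GCTA"], 2),      # sites 1 and 3
            (["A", "A", "G", "-"], 0),                   # singleton G
            (["ACGT", "ACGT", "ACGT", "ACGT"], 0),       # invariant
            (["AR", "AR", "GR", "GR"], 1),               # ambiguity code is not a state
        ],
    )
    def test_examples(self, rows, expected):
        aln = LocusAlignment("x", [f"t{i}" for i in range(len(rows))], rows)
        assert count_informative_sites(aln) == expected

    def test_invariant_under_taxon_and_site_permutation(self, small_alignment):
        rng = np.random.default_rng(0)
        base = count_informative_sites(small_alignment)
        arr = small_alignment.to_array()
        for _ in range(5):
            rows = rng.permutation(arr.shape[0])
            cols = rng.permutation(arr.shape[1])
            shuffled = arr[np.ix_(rows, cols)]
            aln = LocusAlignment(
                "x", [small_alignment.taxa[i] for i in rows],
                ["".join(r) for r in shuffled],
            )
            assert count_informative_sites(aln) == base


class TestCompletenessFilter:
    def _locus(self, n):
        return LocusAlignment("x", [f"t{i}" for i in range(n)], ["ACGT"] * n)

    def test_threshold_is_ceiling(self):
        cfg = MatrixFilterConfig([f"t{i}" for i in range(10)], 0.7)
        assert filter_by_completeness([self._locus(7)], cfg)
        assert not filter_by_completeness([self._locus(6)], cfg)

    def test_full_completeness_requires_all_taxa(self):
        cfg = MatrixFilterConfig([f"t{i}" for i in range(5)], 1.0)
        assert not filter_by_completeness([self._locus(4)], cfg)
        assert filter_by_completeness([self._locus(5)], cfg)

    def test_vanishing_threshold_keeps_everything(self):
        cfg = MatrixFilterConfig([f"t{i}" for i in range(10)], 1e-9)
        assert filter_by_completeness([self._locus(1), self._locus(3)], cfg)

    def test_empty_taxon_set_rejected(self):
        with pytest.raises(ValueError):
            MatrixFilterConfig([], 0.7)


class TestSummaries:
    def test_perfectly_linear_pis(self):
        # PIS = 0.1 * length exactly
        def locus(name, length):
            quarter = length // 10
            rows = []
            block = "AAGG"  # informative column pattern
            for t in range(4):
                row = "".join(
                    block[t] if i < quarter else "C" for i in range(length)
                )
                rows.append(row)
            return LocusAlignment(name, [f"t{i}" for i in range(4)], rows)

        summaries, agg = summarize_loci([locus("a", 100), locus("b", 200)])
        assert [s.pis for s in summaries] == [10, 20]
        assert agg.mean_length == 150 and agg.mean_pis == 15
        assert agg.slope == pytest.approx(0.1)
        assert agg.r_squared == pytest.approx(1.0)

    def test_constant_pis_gives_zero_slope(self):
        loci = [
            LocusAlignment("a", list("wxyz"), ["AAGG" + "C" * 6] * 2 + ["GGAA" + "C" * 6] * 2),
            LocusAlignment("b", list("wxyz"), ["AAGG" + "C" * 16] * 2 + ["GGAA" + "C" * 16] * 2),
        ]
        _, agg = summarize_loci(loci)
        assert agg.slope == pytest.approx(0.0)

    def test_slope_recovered_from_noisy_loci(self):
        # independent closed-form OLS oracle on synthetic (length, pis) pairs
        rng = np.random.default_rng(42)
        lengths = rng.integers(231, 802, size=60)
        pis = 0.4 * lengths + rng.normal(0, 8, size=60)
        x, y = lengths.astype(float), pis
        slope_hat = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
        resid = y - y.mean() - slope_hat * (x - x.mean())
        se = math.sqrt(resid @ resid / (len(x) - 2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope_hat - 0.4) < 2 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_loci([])


class TestConcatenation:
    def test_partition_coordinates(self, tmp_path):
        loci = [
            LocusAlignment("locus2", ["a", "b"], ["C" * 50, "G" * 50]),
            LocusAlignment("locus1", ["a", "b"], ["A" * 100, "T" * 100]),
        ]
        coords = write_concatenated_matrix(loci, tmp_path / "m")
        assert coords == {"locus1": (1, 100), "locus2": (101, 150)}
        partitions = (tmp_path / "m.partitions").read_text()
        assert "DNA, locus1 = 1-100" in partitions
        assert "DNA, locus2 = 101-150" in partitions

    def test_missing_taxon_padded(self, tmp_path):
        loci = [
            LocusAlignment("l1", ["a", "b"], ["A" * 10, "C" * 10]),
            LocusAlignment("l2", ["a"], ["G" * 5]),
        ]
        write_concatenated_matrix(loci, tmp_path / "m")
        fasta = (tmp_path / "m.fasta").read_text()
        b_row = fasta.split(">b\n")[1].split("\n")[0]
        assert b_row == "C" * 10 + "?" * 5

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        loci = [
            LocusAlignment(
                f"uce-{i}",
                ["a", "b", "c"],
                ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(3)],
            )
            for i in range(4)
        ]
        coords = write_concatenated_matrix(loci, tmp_path / "m")
        back = read_concatenated_matrix(tmp_path / "m.fasta", coords)
        assert {a.locus_id: a.seqs for a in back} == {a.locus_id: a.seqs for a in loci}
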