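import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vrflp.digestion import (
    BinaryProfileMatrix,
    EnzymeError,
    band_matrix,
    compile_enzyme,
    default_enzymes,
    digest,
    digest_all,
    find_sites,
    otu_counts,
    read_enzyme_table,
    site_matrix,
)
from vrflp.seqio import SequenceRecord

from _oracles import regex_find_sites

ACGT = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestCompileEnzyme:
    def test_alui(self):
        enz = compile_enzyme("AluI", "AG'CT")
        assert enz.recognition == "AGCT"
        assert enz.cut_offset == 2

    def test_mboi_cut_before_site(self):
        enz = compile_enzyme("MboI", "'GATC")
        assert enz.recognition == "GATC"
        assert enz.cut_offset == 0

    def test_missing_mark_rejected(self):
        with pytest.raises(EnzymeError, match="cut mark"):
            compile_enzyme("X", "AGCT")

    def test_multiple_marks_rejected(self):
        with pytest.raises(EnzymeError, match="cut mark"):
            compile_enzyme("X", "A'GC'T")

    def test_non_iupac_rejected(self):
        with pytest.raises(EnzymeError, match="non-IUPAC"):
            compile_enzyme("X", "AG'CZ")

    def test_typographic_apostrophe_accepted(self):
        enz = compile_enzyme("TaqI", "T’CGA")
        assert (enz.recognition, enz.cut_offset) == ("TCGA", 1)

    def test_builtin_registry(self):
        enzymes = default_enzymes()
        assert [e.name for e in enzymes] == [
            "AluI", "BstUI", "DdeI", "HaeIII", "HhaI",
            "HinfI", "MboI", "MspI", "RsaI", "TaqI",
        ]
        assert all(e.is_palindromic() for e in enzymes)

    def test_enzyme_table_roundtrip(self, tmp_path):
        p = tmp_path / "enz.tsv"
        p.write_text("AluI\tAG'CT\nDdeI\tC'TNAG\n")
        enzymes = read_enzyme_table(p)
        assert [(e.name, e.recognition, e.cut_offset) for e in enzymes] == [
            ("AluI", "AGCT", 2), ("DdeI", "CTNAG", 1),
        ]

    def test_non_palindromic_user_enzyme_warns(self, tmp_path):
        p = tmp_path / "enz.tsv"
        p.write_text("FokI\tGGATG'\n")
        with pytest.warns(UserWarning, match="not.*palindromic"):
            read_enzyme_table(p)


class TestFindSites:
    def test_single_exact_window(self, enzyme_map):
        assert find_sites("AAGCTA", enzyme_map["AluI"]) == [1]

    def test_degenerate_ddei_two_windows(self, enzyme_map):
        # hand enumeration of all length-5 windows against CT[ACGT]AG
        assert find_sites("CTTAGCTGAG", enzyme_map["DdeI"]) == [0, 5]

    def test_sequence_n_inside_recognition_n(self, enzyme_map):
        assert find_sites("GANTC", enzyme_map["HinfI"]) == [0]

    def test_sequence_n_not_subset_of_specific_base(self, enzyme_map):
        assert find_sites("AGNTC", enzyme_map["AluI"]) == []

    def test_gap_rejected(self, enzyme_map):
        with pytest.raises(ValueError, match="gap"):
            find_sites("AG-CT", enzyme_map["AluI"])

    def test_overlapping_matches_reported(self, enzyme_map):
        # GCGCGC: HhaI GCGC matches at 0 and 2
        assert find_sites("GCGCGC", enzyme_map["HhaI"]) == [0, 2]

    def test_short_sequence_empty(self, enzyme_map):
        assert find_sites("AG", enzyme_map["AluI"]) == []

    @given(seq=ACGT)
    @settings(max_examples=200, deadline=None)
    def test_matches_regex_oracle(self, seq):
        for enz in default_enzymes():
            assert find_sites(seq, enz) == regex_find_sites(
                seq, enz.recognition
            )

    @given(seq=ACGT, data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_palindromy_mirrors_site_set(self, seq, data):
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        enz = data.draw(st.sampled_from(default_enzymes()))
        m = len(enz.recognition)
        mirrored = sorted(
            len(seq) - m - s for s in find_sites(seq, enz)
        )
        assert find_sites(rc, enz) == mirrored

    @given(seq=ACGT, pos=st.integers(min_value=0, max_value=300),
           data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_under_site_insertion(self, seq, pos, data):
        enz = data.draw(st.sampled_from(
            [e for e in default_enzymes() if set(e.recognition) <= set("ACGT")]
        ))
        pos = min(pos, len(seq))
        enlarged = seq[:pos] + enz.recognition + seq[pos:]
        assert len(find_sites(enlarged, enz)) >= len(find_sites(seq, enz))


class TestDigest:
    def test_single_cut(self, enzyme_map):
        result = digest("AAGCTA", enzyme_map["AluI"])
        assert result.cut_points == (3,)
        assert result.fragment_lengths == (3, 3)

    def test_identity_digest(self, enzyme_map):
        result = digest("TTTT", enzyme_map["AluI"])
        assert result.cut_points == ()
        assert result.fragment_lengths == (4,)

    def test_ddei_two_cuts(self, enzyme_map):
        result = digest("CTTAGCTGAG", enzyme_map["DdeI"])
        assert result.cut_points == (1, 6)
        assert result.fragment_lengths == (1, 5, 4)

    def test_cut_at_zero_excluded(self, enzyme_map):
        # MboI cuts before the site; a match at position 0 yields no cut
        result = digest("GATCA", enzyme_map["MboI"])
        assert result.match_starts == (0,)
        assert result.cut_points == ()
        assert result.fragment_lengths == (5,)

    @given(seq=ACGT)
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, seq):
        for enz in default_enzymes():
            result = digest(seq, enz)
            assert sum(result.fragment_lengths) == len(seq)
            assert len(result.fragments) == len(result.cut_points) + 1
            # fragments partition the sequence
            bounds = [0]
            for start, end, _ in result.fragments:
                assert start == bounds[-1]
                bounds.append(end)
            assert bounds[-1] == len(seq)


class TestSiteMatrix:
    def test_single_sequence(self, enzyme_map):
        rec = SequenceRecord(id="s1", residues="AAGCTA")
        mat = site_matrix([rec], [enzyme_map["AluI"], enzyme_map["HaeIII"]])
        assert mat.values.tolist() == [[1, 0]]

    def test_presence_not_count(self, enzyme_map):
        rec = SequenceRecord(id="s1", residues="GGCCGGCC")
        mat = site_matrix([rec], [enzyme_map["HaeIII"]])
        assert mat.values.tolist() == [[1]]

    def test_gaps_stripped_before_scanning(self, enzyme_map):
        # the AluI site only exists after removing the alignment gap
        rec = SequenceRecord(id="s1", residues="AG-CT")
        mat = site_matrix([rec], [enzyme_map["AluI"]])
        assert mat.values.tolist() == [[1]]

    def test_empty_input_rejected(self, enzyme_map):
        with pytest.raises(ValueError):
            site_matrix([], [enzyme_map["AluI"]])

    def test_row_and_column_order_preserved(self, enzymes):
        records = [
            SequenceRecord(id=f"s{i}", residues="ACGTACGTACGT")
            for i in range(3)
        ]
        mat = site_matrix(records, enzymes)
        assert mat.row_labels == ("s0", "s1", "s2")
        assert mat.col_labels == tuple(e.name for e in enzymes)


class TestBandMatrix:
    def _digests(self, seqs, enzyme):
        return [
            digest(seq, enzyme, strain=f"s{i + 1}")
            for i, seq in enumerate(seqs)
        ]

    def test_distinct_lengths_distinct_bins(self, enzyme_map):
        # s1 cut into 3+3, s2 uncut of length 6
        ds = self._digests(["AAGCTA", "TTTTTT"], enzyme_map["AluI"])
        mat = band_matrix(ds, tolerance=0.0)
        assert mat.col_labels == ("AluI:3", "AluI:6")
        assert mat.values.tolist() == [[1, 0], [0, 1]]

    def test_identical_digests_identical_rows(self, enzyme_map):
        ds = self._digests(["AAGCTA", "AAGCTA"], enzyme_map["AluI"])
        mat = band_matrix(ds)
        assert (mat.values[0] == mat.values[1]).all()

    def test_tolerance_merges_close_lengths(self, enzyme_map):
        s1 = "T" * 48 + "AGCT" + "T" * 50   # fragments 50, 52
        s2 = "T" * 49 + "AGCT" + "T" * 50   # fragments 51, 52
        ds = self._digests([s1, s2], enzyme_map["AluI"])
        merged = band_matrix(ds, tolerance=0.02)
        exact = band_matrix(ds, tolerance=0.0)
        assert len(merged.col_labels) < len(exact.col_labels)
        assert (merged.values == 1).all()

    def test_negative_tolerance_rejected(self, enzyme_map):
        ds = self._digests(["AAGCTA"], enzyme_map["AluI"])
        with pytest.raises(ValueError):
            band_matrix(ds, tolerance=-0.1)

    def test_missing_strain_for_enzyme_rejected(self, enzyme_map):
        ds = [
            digest("AAGCTA", enzyme_map["AluI"], strain="s1"),
            digest("AAGCTA", enzyme_map["AluI"], strain="s2"),
            digest("GGCC", enzyme_map["HaeIII"], strain="s1"),
        ]
        with pytest.raises(ValueError, match="missing"):
            band_matrix(ds)


class TestOtuCounts:
    def test_no_cuts_is_one(self, enzyme_map):
        counts = otu_counts([digest("TTTT", enzyme_map["AluI"], strain="s1")])
        assert counts.loc["s1", "AluI"] == 1

    def test_two_cuts_is_three(self, enzyme_map):
        counts = otu_counts(
            [digest("CTTAGCTGAG", enzyme_map["DdeI"], strain="s1")]
        )
        assert counts.loc["s1", "DdeI"] == 3

    def test_equals_regex_oracle_cut_count(self, rng, acgt_factory):
        for _ in range(20):
            seq = acgt_factory(rng, 400)
            for enz in default_enzymes():
                d = digest(seq, enz, strain="s")
                starts = regex_find_sites(seq, enz.recognition)
                cuts = {s + enz.cut_offset for s in starts} - {0, len(seq)}
                assert len(d.fragments) == len(cuts) + 1


class TestBinaryProfileMatrix:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            BinaryProfileMatrix(("a",), ("x",), np.array([[2]]))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            BinaryProfileMatrix(("a", "a"), ("x",), np.zeros((2, 1)))

    def test_symbol_frame_roundtrip(self, table2):
        df = table2.to_frame(symbols=True)
        assert set(np.unique(df.values)) <= {"+", "-"}
        back = BinaryProfileMatrix.from_frame(df)
        assert (back.values == table2.values).all()
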