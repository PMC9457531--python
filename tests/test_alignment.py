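import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from orthopath import alignment as al
from orthopath.io_formats import NUCLEOTIDE, SequenceRecord

PROT = st.text(alphabet=al.AA20, min_size=1, max_size=30)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,frame,strand,expected",
        [
            ("ATGGCGTAA", 0, "+", "MA*"),
            ("TTACGCCAT", 0, "-", "MA*"),
            ("ATNGCG", 0, "+", "XA"),
            ("GCNAAA", 0, "+", "XK"),  # even a synonymous-N codon is ambiguous here
            ("AT", 0, "+", ""),
        ],
    )
    def test_known_codons(self, nt, frame, strand, expected):
        assert al.translate(nt, frame, strand) == expected

    def test_against_biopython_oracle(self, rng):
        """Frame translations match Biopython's table-11 translation."""
        nt = "".join(rng.choice(list("ACGT"), 300))
        for strand in "+-":
            s = nt if strand == "+" else al.reverse_complement(nt)
            for frame in (0, 1, 2):
                sliced = s[frame : frame + 3 * ((300 - frame) // 3)]
                expected = str(Seq(sliced).translate(table=11))
                assert al.translate(nt, frame, strand) == expected

    def test_frame_out_of_range(self):
        with pytest.raises(ValueError):
            al.translate("ATG", 3, "+")


class TestSixFrame:
    def test_frame_lengths_nine_nt(self):
        rec = SequenceRecord("c", "", "ATGGCGTAA", NUCLEOTIDE)
        frames = al.six_frame_translate(rec)
        assert len(frames) == 6
        for strand in "+-":
            lens = [len(f.residues) for f in frames if f.strand == strand]
            assert lens == [3, 2, 2]

    def test_palindrome_symmetric(self):
        # reverse complement of ACGCGT is itself
        rec = SequenceRecord("c", "", "ACGCGT", NUCLEOTIDE)
        frames = {(f.strand, f.frame): f.residues for f in al.six_frame_translate(rec)}
        for frame in (0, 1):
            assert frames[("+", frame)] == frames[("-", frame)]

    def test_too_short_contig(self, caplog):
        rec = SequenceRecord("tiny", "", "AC", NUCLEOTIDE)
        with caplog.at_level("WARNING"):
            assert al.six_frame_translate(rec) == []
        assert "tiny" in caplog.text


class TestScoringMatrix:
    def test_ambiguous_symbols_score_minimum(self, b62):
        assert b62.ambiguous_score == -4
        for ch in "AX*":
            assert b62.score("X", ch) == -4
            assert b62.score("*", ch) == -4

    def test_ncbi_format_file_loads(self, tmp_path, b62):
        from Bio.Align import substitution_matrices

        path = tmp_path / "BLOSUM62.txt"
        path.write_text(str(substitution_matrices.load("BLOSUM62")))
        loaded = al.load_matrix(path)
        assert np.array_equal(loaded.scores, b62.scores)


class TestSmithWaterman:
    def test_self_alignment(self, b62):
        a = al.smith_waterman("MKVLA", "MKVLA", b62)
        assert a.identity_pct == 100.0
        assert a.query_coverage_pct == 100.0
        assert a.score == sum(b62.score(c, c) for c in "MKVLA")

    def test_exact_substring(self, b62):
        a = al.smith_waterman("MKVLA", "XXXMKVLAXXX", b62)
        assert a.query_coverage_pct == 100.0
        assert (a.subject_start, a.subject_end) == (4, 8)
        assert a.aligned_query == a.aligned_subject == "MKVLA"

    def test_mkv_vs_aaa_matches_enumeration(self, b62, brute_force_local_score):
        a = al.smith_waterman("MKV", "AAA", b62)
        assert a.score == brute_force_local_score("MKV", "AAA", b62)

    def test_empty_sequence_rejected(self, b62):
        with pytest.raises(ValueError):
            al.smith_waterman("", "MKV", b62)

    def test_score_only_agrees_with_traceback_path(self, b62, rng):
        for _ in range(20):
            q = "".join(rng.choice(list(al.AA20), rng.integers(5, 40)))
            s = "".join(rng.choice(list(al.AA20), rng.integers(5, 80)))
            assert al.sw_score(q, s, b62) == al.smith_waterman(q, s, b62).score

    def test_oracle_equivalence_random_pairs(self, b62, brute_force_local_score, rng):
        """DP score equals exhaustive enumeration on random short pairs."""
        for _ in range(40):
            a = "".join(rng.choice(list(al.AA20), rng.integers(2, 9)))
            b = "".join(rng.choice(list(al.AA20), rng.integers(2, 9)))
            assert al.sw_score(a, b, b62) == brute_force_local_score(a, b, b62)

    @given(a=PROT, b=PROT)
    def test_score_symmetry(self, a, b):
        b62 = al.blosum62()
        assert al.sw_score(a, b, b62) == al.sw_score(b, a, b62)

    @given(a=PROT, b=PROT, extra=PROT)
    def test_subject_extension_monotone(self, a, b, extra):
        b62 = al.blosum62()
        assert al.sw_score(a, b + extra, b62) >= al.sw_score(a, b, b62)

    def test_gapped_alignment_percentages_count_gap_columns(self, b62):
        # internal single-residue deletion: flanks outweigh the gap cost
        a = al.smith_waterman("MKVLACWWWCALVKM", "MKVLACWWCALVKM", b62)
        assert a.aligned_subject.count("-") == 1
        cols = len(a.aligned_query)
        assert cols == 15
        assert a.identity_pct == pytest.approx(100.0 * 14 / cols)

    def test_stop_codons_cannot_inflate_similarity(self, b62):
        # subject is the query interrupted by stops: stops score -4
        a = al.smith_waterman("WWWWWW", "WWW**WWW", b62)
        assert a.score <= 6 * b62.score("W", "W")

    def test_invariants_on_random_pairs(self, b62, rng):
        for _ in range(50):
            q = "".join(rng.choice(list(al.AA20), rng.integers(3, 60)))
            s = "".join(rng.choice(list(al.AA20), rng.integers(3, 60)))
            a = al.smith_waterman(q, s, b62)
            assert 0 <= a.identity_pct <= a.similarity_pct <= 100
            assert 0 <= a.query_identity_pct <= a.query_similarity_pct <= 100
            assert len(a.aligned_query) == len(a.aligned_subject)
            degapped_q = a.aligned_query.replace("-", "")
            assert degapped_q == q[a.query_start - 1 : a.query_end]
            degapped_s = a.aligned_subject.replace("-", "")
            assert degapped_s == s[a.subject_start - 1 : a.subject_end]


class TestGlobalAlign:
    def test_single_gap_column(self, b62):
        aa, ab, score = al.global_align("MKVLA", "MKLA", b62)
        assert (aa, ab) == ("MKVLA", "MK-LA")
        expected = (
            b62.score("M", "M") + b62.score("K", "K") - 12
            + b62.score("L", "L") + b62.score("A", "A")
        )
        assert score == expected

    def test_identical_sequences_no_gaps(self, b62):
        aa, ab, score = al.global_align("MKVLA", "MKVLA", b62)
        assert aa == ab == "MKVLA"
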