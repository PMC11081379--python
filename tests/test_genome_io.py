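import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compoundg4 import (
    CpgIslandParams,
    Genome,
    GenomicInterval,
    extract_sequence,
    find_cpg_islands,
    gc_content,
    read_fasta,
    read_peaks_bed,
    reverse_complement,
    scan_iupac_motif,
    write_peaks_bed,
)
from compoundg4.peak_annotation import PeakRecord

dna = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestFasta:
    def test_case_normalized(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgT\n")
        assert read_fasta(p)["chr1"] == "ACGT"

    def test_multi_record_wrapped(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\nACGT\n>chr2\nTTTT\n")
        g = read_fasta(p)
        assert len(g) == 2
        assert g["chr1"] == "ACGTACGT"
        assert len(g["chr2"]) == 4

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nAC\n>chr1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_invalid_character_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXT\n")
        with pytest.raises(ValueError, match="non-IUPAC"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "absent.fa")


class TestExtract:
    def test_half_open_plus(self):
        g = Genome({"chr1": "ACGTACGT"})
        assert extract_sequence(g, GenomicInterval("chr1", 2, 5, "+")) == "GTA"

    def test_minus_is_revcomp(self):
        g = Genome({"chr1": "ACGTACGT"})
        assert extract_sequence(g, GenomicInterval("chr1", 2, 5, "-")) == "TAC"

    def test_out_of_bounds(self):
        g = Genome({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError, match="exceeds"):
            extract_sequence(g, GenomicInterval("chr1", 6, 10))

    def test_unknown_chrom(self):
        g = Genome({"chr1": "ACGT"})
        with pytest.raises(KeyError):
            extract_sequence(g, GenomicInterval("chrX", 0, 2))

    @settings(derandomize=True, max_examples=50)
    @given(seq=st.text(alphabet="ACGTN", min_size=4, max_size=40))
    def test_minus_equals_revcomp_of_plus(self, seq):
        g = Genome({"c": seq})
        iv_p = GenomicInterval("c", 1, len(seq), "+")
        iv_m = GenomicInterval("c", 1, len(seq), "-")
        assert extract_sequence(g, iv_m) == reverse_complement(
            extract_sequence(g, iv_p)
        )


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected", [("GGGA", "TCCC"), ("", ""), ("N", "N"), ("ACGT", "ACGT")]
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(seq=dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGGG", 1.0), ("NNAT", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_all_n_is_nan(self):
        assert math.isnan(gc_content("NNNN"))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestCpgIslands:
    def test_pure_cg_run_called(self):
        g = Genome({"chr1": "CG" * 150})
        assert find_cpg_islands(g) == [GenomicInterval("chr1", 0, 300)]

    def test_at_only_empty(self):
        assert find_cpg_islands(Genome({"chr1": "AT" * 150})) == []

    def test_short_run_below_min_length(self):
        g = Genome({"chr1": "AT" * 100 + "CG" * 75 + "AT" * 100})
        assert find_cpg_islands(g) == []

    def test_flanked_run_trimmed_to_core(self):
        g = Genome({"chr1": "AT" * 100 + "CG" * 150 + "AT" * 100})
        assert find_cpg_islands(g) == [GenomicInterval("chr1", 200, 500)]

    def test_gc_without_cpg_fails_obs_exp(self):
        # G-then-C halves are GC-rich but contain no CpG dinucleotide at all
        g = Genome({"chr1": "G" * 300 + "C" * 300})
        assert find_cpg_islands(g) == []

    def test_output_sorted_disjoint_min_length(self, default_dataset):
        islands = find_cpg_islands(default_dataset.genome, CpgIslandParams())
        prev_by_chrom = {}
        for iv in islands:
            assert len(iv) >= 200
            if iv.chrom in prev_by_chrom:
                assert iv.start >= prev_by_chrom[iv.chrom]
            prev_by_chrom[iv.chrom] = iv.end
        assert islands == sorted(islands, key=lambda i: (i.chrom, i.start))


class TestIupacScan:
    def test_simple_match(self):
        assert scan_iupac_motif("AGGT", "GGN") == [(1, "+")]

    def test_degenerate_15mer(self):
        assert scan_iupac_motif("GGAGGCTGCGGAAGC", "GGVGGCNGVGGHDGS") == [(0, "+")]

    def test_empty_sequence(self):
        assert scan_iupac_motif("", "GG") == []

    def test_overlapping_matches_reported(self):
        assert scan_iupac_motif("GGGG", "GG") == [(0, "+"), (1, "+"), (2, "+")]

    def test_minus_strand_forward_coordinates(self):
        # CCT on the forward strand is AGG on the reverse
        hits = scan_iupac_motif("ACCTA", "AGG", both_strands=True)
        assert hits == [(1, "-")]

    def test_n_base_matches_only_code_n(self):
        assert scan_iupac_motif("GNG", "GSG") == []
        assert scan_iupac_motif("GNG", "GNG") == [(0, "+")]

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_iupac_motif("ACGT", "GXG")

    @settings(derandomize=True, max_examples=50)
    @given(seq=st.text(alphabet="ACGT", min_size=3, max_size=30))
    def test_all_n_motif_matches_everywhere(self, seq):
        hits = scan_iupac_motif(seq, "NNN")
        assert len(hits) == len(seq) - 2


class TestPeaksBed:
    def test_parse(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t60\tp1\t3.2\n")
        peaks = read_peaks_bed(p)
        assert peaks == [
            PeakRecord(interval=GenomicInterval("chr1", 10, 60), score=3.2, name="p1")
        ]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("")
        assert read_peaks_bed(p) == []

    @pytest.mark.parametrize(
        "line,err",
        [
            ("chr1\t60\t10\tp1\t1", "start >= end"),
            ("chr1\t10\t60\tp1\t-1", "negative score"),
            ("chr1\t10\t60", "5 BED columns"),
            ("chr1\tten\t60\tp1\t1", "malformed"),
        ],
    )
    def test_malformed(self, tmp_path, line, err):
        p = tmp_path / "p.bed"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=err):
            read_peaks_bed(p)

    def test_round_trip_bit_exact(self, tmp_path):
        src = tmp_path / "a.bed"
        dst = tmp_path / "b.bed"
        src.write_text("chr1\t10\t60\tp1\t3.2\nchr2\t0\t5\tp2\t0.25\n")
        write_peaks_bed(read_peaks_bed(src), dst)
        assert read_peaks_bed(dst) == read_peaks_bed(src)
        assert dst.read_text() == src.read_text()
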