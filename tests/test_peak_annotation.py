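import numpy as np
import pytest

from compoundg4 import (
    GeneModel,
    Genome,
    GenomicInterval,
    compare_top_bottom_gc,
    cpg_overlap_fraction,
    motif_enrichment,
    rank_peaks,
    tss_distance_histogram,
)
from compoundg4.genome_io import IUPAC_CODES
from compoundg4.peak_annotation import PeakRecord

from conftest import random_dna


def mk_peak(chrom, start, end, score=1.0, name="."):
    return PeakRecord(interval=GenomicInterval(chrom, start, end), score=score, name=name)


class TestRankPeaks:
    def test_descending_score(self):
        peaks = [
            mk_peak("chr1", 0, 10, 3.2),
            mk_peak("chr1", 20, 30, 5.1),
            mk_peak("chr1", 40, 50, 1.0),
        ]
        ranked = rank_peaks(peaks)
        assert [p.score for p in ranked] == [5.1, 3.2, 1.0]
        assert [p.rank for p in ranked] == [1, 2, 3]

    def test_ties_by_coordinate(self):
        peaks = [mk_peak("chr2", 5, 10, 2.0), mk_peak("chr1", 50, 60, 2.0),
                 mk_peak("chr1", 5, 10, 2.0)]
        ranked = rank_peaks(peaks)
        assert [(p.interval.chrom, p.interval.start) for p in ranked] == [
            ("chr1", 5), ("chr1", 50), ("chr2", 5)
        ]

    def test_empty(self):
        assert rank_peaks([]) == []


class TestGcComparison:
    def test_separated_groups(self):
        rng = np.random.default_rng(3)
        gc_block = random_dna(rng, 2000, gc=0.7)
        at_block = random_dna(rng, 2000, gc=0.3)
        genome = Genome({"hi": gc_block, "lo": at_block})
        peaks = [mk_peak("hi", i * 100, i * 100 + 100, score=10 - i * 0.1) for i in range(10)]
        peaks += [mk_peak("lo", i * 100, i * 100 + 100, score=1 - i * 0.01) for i in range(10)]
        ranked = rank_peaks(peaks)
        cmp_ = compare_top_bottom_gc(ranked, genome, 10)
        assert cmp_.mean_top - cmp_.mean_bottom == pytest.approx(0.4, abs=0.08)
        assert cmp_.pvalue < 1e-3

    def test_identical_sequences_p_one(self):
        genome = Genome({"c": "ACGT" * 100})
        peaks = [mk_peak("c", 0, 40, score=float(i)) for i in range(6)]
        ranked = rank_peaks(peaks)
        cmp_ = compare_top_bottom_gc(ranked, genome, 3)
        assert cmp_.mean_top == cmp_.mean_bottom
        assert cmp_.pvalue == 1.0

    def test_degenerate_cohort_of_two(self):
        genome = Genome({"c": "ACGTACGTGGCC"})
        ranked = rank_peaks([mk_peak("c", 0, 4, 2.0), mk_peak("c", 8, 12, 1.0)])
        cmp_ = compare_top_bottom_gc(ranked, genome, 1)
        assert np.isfinite(cmp_.statistic)

    def test_groups_must_be_disjoint(self):
        genome = Genome({"c": "ACGT" * 10})
        ranked = rank_peaks([mk_peak("c", 0, 4, float(i)) for i in range(3)])
        with pytest.raises(ValueError, match="exceeds cohort"):
            compare_top_bottom_gc(ranked, genome, 2)


class TestCpgOverlap:
    def test_half_overlap(self):
        peaks = [mk_peak("chr1", 0, 100), mk_peak("chr1", 500, 600)]
        islands = [GenomicInterval("chr1", 50, 60)]
        assert cpg_overlap_fraction(peaks, islands) == 0.5

    def test_no_islands(self):
        assert cpg_overlap_fraction([mk_peak("chr1", 0, 10)], []) == 0.0

    def test_half_open_abutment_no_overlap(self):
        peaks = [mk_peak("chr1", 100, 200)]
        islands = [GenomicInterval("chr1", 200, 300)]
        assert cpg_overlap_fraction(peaks, islands) == 0.0

    def test_invariant_to_island_fragmentation(self):
        rng = np.random.default_rng(17)
        peaks = [
            mk_peak("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 5000, size=40)
        ]
        islands = [GenomicInterval("chr1", 100, 400), GenomicInterval("chr1", 900, 1300)]
        fragmented = [
            GenomicInterval("chr1", 100, 250), GenomicInterval("chr1", 250, 400),
            GenomicInterval("chr1", 900, 1000), GenomicInterval("chr1", 1000, 1200),
            GenomicInterval("chr1", 1200, 1300),
        ]
        assert cpg_overlap_fraction(peaks, islands) == cpg_overlap_fraction(
            peaks, fragmented
        )


class TestTssHistogram:
    GENES = [GeneModel("gp", "chr1", "+", 10_000), GeneModel("gm", "chr2", "-", 10_000)]

    def bin_of(self, chrom, midpoint):
        h = tss_distance_histogram(
            [mk_peak(chrom, midpoint - 5, midpoint + 5)], self.GENES
        )
        assert sum(h.counts) == 1
        return h.labels[int(np.argmax(h.counts))]

    def test_downstream_plus_gene(self):
        assert self.bin_of("chr1", 12_000) == "[0,5000)"

    def test_downstream_minus_gene_sign_flip(self):
        assert self.bin_of("chr2", 8_000) == "[0,5000)"

    def test_upstream_minus_gene(self):
        assert self.bin_of("chr2", 12_000) == "[-5000,0)"

    def test_midpoint_at_tss_zero_distance(self):
        assert self.bin_of("chr1", 10_000) == "[0,5000)"

    def test_beyond_outer_edge_in_end_bin(self):
        genes = [GeneModel("g", "chr1", "+", 1000)]
        h = tss_distance_histogram([mk_peak("chr1", 900_000, 900_010)], genes)
        assert h.counts[-1] == 1

    def test_unassigned_bucket_and_conservation(self):
        peaks = [mk_peak("chr1", 11_000, 11_010), mk_peak("chrX", 0, 10)]
        h = tss_distance_histogram(peaks, self.GENES)
        assert h.unassigned == 1
        assert sum(h.counts) + h.unassigned == len(peaks)

    def test_requires_genes(self):
        with pytest.raises(ValueError):
            tss_distance_histogram([mk_peak("chr1", 0, 10)], [])


class TestMotifEnrichment:
    MOTIF = "GGVGGCNGVGGHDGS"
    INSTANCE = "GGAGGCTGCGGAAGC"

    def test_embedded_motifs_enriched(self):
        rng = np.random.default_rng(8)
        chrom = []
        peaks, background = [], []
        pos = 0
        for i in range(10):
            flank = random_dna(rng, 40, gc=0.3)
            block = flank + self.INSTANCE + flank
            chrom.append(block)
            peaks.append(mk_peak("c", pos, pos + len(block), 5.0, f"p{i}"))
            pos += len(block)
        for i in range(10):
            block = "AT" * 50
            chrom.append(block)
            background.append(mk_peak("c", pos, pos + len(block), 1.0, f"b{i}"))
            pos += len(block)
        genome = Genome({"c": "".join(chrom)})
        enr = motif_enrichment(peaks, genome, self.MOTIF, background)
        assert enr.peak_count >= 10
        assert enr.background_count == 0
        assert enr.fold > 10
        assert enr.pvalue < 1e-6

    def test_identical_sets_fold_one(self):
        rng = np.random.default_rng(9)
        genome = Genome({"c": random_dna(rng, 4000, gc=0.5)})
        peaks = [mk_peak("c", i * 400, (i + 1) * 400, 1.0) for i in range(10)]
        enr = motif_enrichment(peaks, genome, self.MOTIF, peaks)
        assert enr.fold == pytest.approx(1.0)

    def test_background_required(self):
        genome = Genome({"c": "ACGT" * 100})
        with pytest.raises(ValueError):
            motif_enrichment([mk_peak("c", 0, 100)], genome, self.MOTIF, [])

    def test_density_matches_closed_form(self):
        # per-position match probability under i.i.d. bases, both strands
        probs = {"A": 0.2, "C": 0.3, "G": 0.3, "T": 0.2}
        p_match = 1.0
        for code in self.MOTIF:
            p_match *= sum(probs[b] for b in IUPAC_CODES[code])
        rng = np.random.default_rng(123)
        length = 3_000_000
        seq = "".join(
            np.array(list("ACGT"))[
                rng.choice(4, size=length, p=[0.2, 0.3, 0.3, 0.2])
            ]
        )
        genome = Genome({"c": seq})
        n_peaks = 100
        w = length // n_peaks
        bg = [mk_peak("c", i * w, (i + 1) * w, 1.0, f"b{i}") for i in range(n_peaks)]
        enr = motif_enrichment(bg, genome, self.MOTIF, bg)
        n_pos = 2 * n_peaks * (w - len(self.MOTIF) + 1)
        expected = n_pos * p_match
        se = np.sqrt(n_pos * p_match * (1 - p_match))
        assert abs(enr.peak_count - expected) <= 3 * se
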