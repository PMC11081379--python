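"""Cohort-level annotation of ranked peaks.

Peaks arrive as intervals scored by -log10 FDR.  The module ranks them,
compares GC content of the top-n versus bottom-n by a two-sided rank-sum
test, intersects peaks with CpG islands, histograms signed distances to the
nearest transcription start site (downstream positive, strand-aware), and
quantifies the density of a degenerate IUPAC motif in peaks against a
background peak set.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .genome_io import (
    GeneModel,
    Genome,
    GenomicInterval,
    extract_sequence,
    gc_content,
    scan_iupac_motif,
)

#: Default signed TSS-distance bin edges in bp (downstream positive).
DEFAULT_TSS_BIN_EDGES = (-500_000, -50_000, -5_000, 0, 5_000, 50_000, 500_000)


@dataclass(frozen=True)
class PeakRecord:
    """One scored peak; rank 1 = most significant, assigned by rank_peaks."""

    interval: GenomicInterval
    score: float
    name: str = "."
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score (-log10 FDR) must be >= 0")


@dataclass(frozen=True)
class GcComparison:
    """Top-n vs bottom-n GC content with a two-sided rank-sum test."""

    n: int
    mean_top: float
    mean_bottom: float
    median_top: float
    median_bottom: float
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class TssHistogram:
    """Counts of peaks per signed TSS-distance bin (downstream positive).

    Outer bins absorb distances beyond the listed edges; peaks on
    chromosomes without genes land in ``unassigned``.
    """

    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]
    unassigned: int

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.bin_edges
        return tuple(f"[{e[i]},{e[i + 1]})" for i in range(len(e) - 1))

    def modal_bin(self) -> str:
        return self.labels[int(np.argmax(self.counts))]


@dataclass(frozen=True)
class MotifEnrichment:
    """Motif density (per kb, both strands) in peaks vs background."""

    motif: str
    peak_count: int
    background_count: int
    peak_bp: int
    background_bp: int
    peak_density: float
    background_density: float
    fold: float
    pvalue: float


def rank_peaks(peaks: list[PeakRecord]) -> list[PeakRecord]:
    """Assign ranks 1..n by descending score; ties by (chrom, start)."""
    ordered = sorted(
        peaks,
        key=lambda p: (-p.score, p.interval.chrom, p.interval.start),
    )
    return [replace(p, rank=i + 1) for i, p in enumerate(ordered)]


def peak_gc(peak: PeakRecord, genome: Genome) -> float:
    return gc_content(extract_sequence(genome, peak.interval))


def compare_top_bottom_gc(
    ranked: list[PeakRecord], genome: Genome, n: int
) -> GcComparison:
    """Rank-sum comparison of GC content, top-n vs bottom-n peaks.

    Requires 2n <= cohort size so the groups are disjoint.
    """
    if 2 * n > len(ranked):
        raise ValueError(f"2n = {2 * n} exceeds cohort size {len(ranked)}")
    ordered = sorted(ranked, key=lambda p: p.rank if p.rank else 0)
    top = [peak_gc(p, genome) for p in ordered[:n]]
    bottom = [peak_gc(p, genome) for p in ordered[-n:]]
    stat, p = stats.ranksums(top, bottom)
    return GcComparison(
        n=n,
        mean_top=float(np.mean(top)),
        mean_bottom=float(np.mean(bottom)),
        median_top=float(np.median(top)),
        median_bottom=float(np.median(bottom)),
        statistic=float(stat),
        pvalue=float(p),
    )


def _merge_intervals(
    intervals: list[GenomicInterval],
) -> dict[str, tuple[list[int], list[int]]]:
    """Per-chrom sorted, merged (starts, ends) arrays for overlap queries."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts: list[int] = []
        ends: list[int] = []
        for iv in ivs:
            if starts and iv.start <= ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        merged[chrom] = (starts, ends)
    return merged


def cpg_overlap_fraction(
    peaks: list[PeakRecord], islands: list[GenomicInterval]
) -> float:
    """Fraction of peaks sharing >= 1 bp with any island (half-open)."""
    if not peaks:
        return 0.0
    merged = _merge_intervals(islands)
    n_overlap = 0
    for p in peaks:
        entry = merged.get(p.interval.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # candidate island: the last one starting before the peak end
        i = bisect.bisect_left(starts, p.interval.end)
        if i > 0 and ends[i - 1] > p.interval.start:
            n_overlap += 1
    return n_overlap / len(peaks)


def tss_distance_histogram(
    peaks: list[PeakRecord],
    genes: list[GeneModel],
    bin_edges: tuple[int, ...] = DEFAULT_TSS_BIN_EDGES,
) -> TssHistogram:
    """Bin signed peak-midpoint distances to the nearest same-chrom TSS.

    The sign is flipped for minus-strand genes so that downstream of
    transcription is positive.  Distances beyond the outer edges count in
    the extreme bins (open ends); a midpoint exactly at the TSS has distance
    0 and falls in the first non-negative bin.
    """
    if not genes:
        raise ValueError("need at least one gene")
    edges = tuple(bin_edges)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand))
    for lst in tss_by_chrom.values():
        lst.sort()
    counts = [0] * (len(edges) - 1)
    unassigned = 0
    for p in peaks:
        entries = tss_by_chrom.get(p.interval.chrom)
        if not entries:
            unassigned += 1
            continue
        mid = p.interval.midpoint
        positions = [t for t, _ in entries]
        i = bisect.bisect_left(positions, mid)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                tss, strand = entries[j]
                d = abs(mid - tss)
                if best is None or d < best[0]:
                    best = (d, tss, strand)
        assert best is not None
        _, tss, strand = best
        signed = mid - tss if strand == "+" else tss - mid
        k = int(np.searchsorted(edges, signed, side="right")) - 1
        k = min(max(k, 0), len(counts) - 1)  # open end-bins
        counts[k] += 1
    return TssHistogram(bin_edges=edges, counts=tuple(counts), unassigned=unassigned)


def _motif_counts(
    peaks: list[PeakRecord], genome: Genome, motif: str
) -> tuple[int, int]:
    """(occurrences on both strands, total bp) over a peak set."""
    count = 0
    bp = 0
    for p in peaks:
        seq = extract_sequence(
            genome, replace(p.interval, strand="+") if p.interval.strand == "-" else p.interval
        )
        count += len(scan_iupac_motif(seq, motif, both_strands=True))
        bp += len(seq)
    return count, bp


def motif_enrichment(
    peaks: list[PeakRecord],
    genome: Genome,
    motif: str,
    background_peaks: list[PeakRecord],
) -> MotifEnrichment:
    """Motif density per kb in peaks vs background, with fold and binomial p.

    fold = (peak density + eps) / (background density + eps) with eps one
    pseudocount spread over the combined bp, so motif-free backgrounds give
    a finite fold.  The one-sided binomial test treats the per-position
    background match rate as the null for the peak occurrence count.
    """
    if not background_peaks:
        raise ValueError("background peak set must be non-empty")
    pc, pbp = _motif_counts(peaks, genome, motif)
    bc, bbp = _motif_counts(background_peaks, genome, motif)
    if pbp == 0 or bbp == 0:
        raise ValueError("zero total bp in peaks or background")
    p_density = pc / pbp * 1000.0
    b_density = bc / bbp * 1000.0
    eps = 1000.0 / (pbp + bbp)  # one pseudocount over combined bp, per kb
    fold = (p_density + eps) / (b_density + eps)
    m = len(motif)
    # scanned positions per strand, both strands
    n_pos = sum(2 * max(len(p.interval) - m + 1, 0) for p in peaks)
    n_bg_pos = sum(2 * max(len(p.interval) - m + 1, 0) for p in background_peaks)
    null_rate = min(max(bc / n_bg_pos if n_bg_pos else 0.0, 1.0 / (n_bg_pos + n_pos)), 1.0)
    pvalue = float(
        stats.binomtest(pc, n_pos, null_rate, alternative="greater").pvalue
    ) if n_pos else 1.0
    return MotifEnrichment(
        motif=motif,
        peak_count=pc,
        background_count=bc,
        peak_bp=pbp,
        background_bp=bbp,
        peak_density=p_density,
        background_density=b_density,
        fold=fold,
        pvalue=pvalue,
    )
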