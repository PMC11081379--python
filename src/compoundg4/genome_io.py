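"""Sequence and interval plumbing.

FASTA and BED reading/writing, strand-aware sequence extraction, GC content,
sliding-window CpG-island calling, and IUPAC degenerate-motif scanning.  All
coordinates are 0-based, half-open (BED convention) throughout the package.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate nucleotide codes mapped to the set of concrete bases
#: they stand for.  An ``N`` in the *sequence* matches only the code ``N``.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """Mapping from chromosome name to an uppercase DNA string over ACGTN."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"non-IUPAC characters in {name!r}: {sorted(bad)}"
                )
            self._seqs[name] = seq

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def chrom_length(self, chrom: str) -> int:
        return len(self[chrom])


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene: TSS, strand and ordered non-overlapping exons."""

    name: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError("exon chrom differs from gene chrom")
            if ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end


@dataclass(frozen=True)
class CpgIslandParams:
    """Sliding-window CpG-island thresholds (Gardiner-Garden & Frommer style).

    Defaults: merged length >= 200 bp, window GC > 0.5, observed/expected
    CpG > 0.6, computed in 200-bp windows advanced 1 bp at a time.
    """

    min_length: int = 200
    min_gc: float = 0.5
    min_obs_exp: float = 0.6
    window: int = 200
    step: int = 1

    def __post_init__(self) -> None:
        if not (self.min_length >= self.window > 0):
            raise ValueError("require min_length >= window > 0")
        if not (0 < self.min_gc <= 1):
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-record, wrapped or unwrapped) FASTA file into a Genome.

    Parsing is delegated to Bio.SeqIO; sequences are uppercased, and
    duplicate record names or non-IUPAC characters raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sequence operations

def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Sequence of ``interval``; reverse-complemented for '-' strand."""
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds chromosome length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N is excluded from the denominator.

    Returns ``nan`` when the sequence has no unambiguous bases.  Raises on
    an empty sequence.
    """
    if not seq:
        raise ValueError("gc_content of empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return math.nan
    return gc / denom


# ---------------------------------------------------------------------------
# CpG islands

def find_cpg_islands(
    genome: Genome, params: CpgIslandParams | None = None
) -> list[GenomicInterval]:
    """Call CpG islands by merging passing sliding windows.

    A window of ``params.window`` bp passes when its GC fraction exceeds
    ``min_gc`` and its observed/expected CpG ratio (#CG * window / (#C * #G),
    requiring #C * #G > 0) is at least ``min_obs_exp``.  Overlapping or
    abutting passing windows are merged; each merged segment is then trimmed
    from its ends (weak, non-G/C ends first) until the segment as a whole
    meets both thresholds, and dropped if it falls below ``min_length``
    before passing.  Output is sorted and non-overlapping.
    """
    if params is None:
        params = CpgIslandParams()
    islands: list[GenomicInterval] = []
    for chrom in genome:
        seq = genome[chrom]
        n = len(seq)
        w = params.window
        if n < w:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        # CpG dinucleotide starts
        is_cg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cg[:-1] = is_c[:-1] & is_g[1:]
        cum_c = np.concatenate(([0], np.cumsum(is_c)))
        cum_g = np.concatenate(([0], np.cumsum(is_g)))
        cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
        starts = np.arange(0, n - w + 1, params.step)
        c = cum_c[starts + w] - cum_c[starts]
        g = cum_g[starts + w] - cum_g[starts]
        # count only CpG pairs fully inside the window
        cg = cum_cg[starts + w - 1] - cum_cg[starts]
        gc_frac = (c + g) / w
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where(c * g > 0, cg * w / np.maximum(c * g, 1), 0.0)
        passing = (gc_frac > params.min_gc) & (obs_exp > params.min_obs_exp)

        def segment_ok(lo: int, hi: int) -> bool:
            length = hi - lo
            c = cum_c[hi] - cum_c[lo]
            g = cum_g[hi] - cum_g[lo]
            cg = cum_cg[hi - 1] - cum_cg[lo] if hi - lo > 1 else 0
            if (c + g) / length <= params.min_gc:
                return False
            if c * g == 0:
                return False
            return cg * length / (c * g) > params.min_obs_exp

        def trim(lo: int, hi: int) -> GenomicInterval | None:
            # islands start and end on a strong base; shrink until the whole
            # segment meets the thresholds
            while hi - lo >= params.min_length:
                while lo < hi and seq[lo] not in "GC":
                    lo += 1
                while hi > lo and seq[hi - 1] not in "GC":
                    hi -= 1
                if hi - lo < params.min_length:
                    return None
                if segment_ok(lo, hi):
                    return GenomicInterval(chrom, lo, hi)
                lo += 1
            return None

        # merge passing windows into maximal runs, then trim each
        run_start: int | None = None
        run_end = 0
        for s, ok in zip(starts.tolist(), passing.tolist()):
            if ok:
                if run_start is None or s > run_end:
                    if run_start is not None:
                        iv = trim(run_start, run_end)
                        if iv:
                            islands.append(iv)
                    run_start = s
                run_end = s + w
        if run_start is not None:
            iv = trim(run_start, run_end)
            if iv:
                islands.append(iv)
    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    return islands


# ---------------------------------------------------------------------------
# IUPAC motif scanning

def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for code in motif.upper():
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r}")
        bases = "".join(sorted(IUPAC_CODES[code]))
        if code == "N":
            bases += "N"  # unknown base matches only the wildcard code
        parts.append(f"[{bases}]")
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_iupac_motif(
    seq: str, motif: str, both_strands: bool = False
) -> list[tuple[int, str]]:
    """All (position, strand) matches of an IUPAC motif, overlapping included.

    Minus-strand matches (of the motif against the reverse complement) are
    reported in forward coordinates of ``seq``.
    """
    pattern = _iupac_regex(motif)
    seq = seq.upper()
    hits = [(m.start(), "+") for m in pattern.finditer(seq)]
    if both_strands:
        rc = reverse_complement(seq)
        m_len = len(motif)
        for m in pattern.finditer(rc):
            hits.append((len(seq) - m.start() - m_len, "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# BED / gene-model I/O

def read_peaks_bed(path: str | Path):
    """Read a BED5+ peak file; column 5 is -log10 FDR.

    Returns a list of :class:`~compoundg4.peak_annotation.PeakRecord` with
    no ranks assigned.
    """
    from .peak_annotation import PeakRecord

    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{ln}: expected >= 5 BED columns")
            chrom, start, end, name, score = fields[:5]
            try:
                start_i, end_i, score_f = int(start), int(end), float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed field ({exc})") from None
            if start_i >= end_i:
                raise ValueError(f"{path}:{ln}: start >= end")
            if score_f < 0:
                raise ValueError(f"{path}:{ln}: negative score")
            peaks.append(
                PeakRecord(
                    interval=GenomicInterval(chrom, start_i, end_i),
                    score=score_f,
                    name=name,
                )
            )
    return peaks


def write_peaks_bed(peaks: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.name}\t{p.score:g}\n"
            )


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score default to '.' and 0)."""
    intervals = list(intervals)
    names = list(names) if names is not None else ["."] * len(intervals)
    scores = list(scores) if scores is not None else [0.0] * len(intervals)
    with open(path, "w") as fh:
        for iv, nm, sc in zip(intervals, names, scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t{sc:g}\t{iv.strand}\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (first 3-6 BED columns)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Gene models as TSV: name, chrom, strand, tss, comma-joined exon spans."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstrand\ttss\texons\n")
        for g in genes:
            spans = ",".join(f"{e.start}-{e.end}" for e in g.exons)
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tss}\t{spans}\n")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("name\t"):
            raise ValueError(f"{path}: missing gene TSV header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, chrom, strand, tss, spans = line.split("\t")
            exons = []
            if spans:
                for span in spans.split(","):
                    s, e = span.split("-")
                    exons.append(GenomicInterval(chrom, int(s), int(e), strand))
            genes.append(GeneModel(name, chrom, strand, int(tss), tuple(exons)))
    return genes
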