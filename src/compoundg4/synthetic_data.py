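"""Synthetic labelled genome for end-to-end pipeline testing.

The generator emits a toy genome whose statistical structure mirrors a
chromatin-association peak cohort over transcribed, GC-rich sequence:

* genes with TSSs and downstream exons;
* *compound* cassettes inside exons — two quadruplex-forming sequences on
  the template strand plus one on the non-template strand, all under one
  peak-width footprint;
* *single* cassettes — one non-template-strand quadruplex;
* GC-rich CpG-island-like blocks over cassette footprints and near a
  configurable fraction of TSSs;
* background peaks on footprints constructively free of G- or C-runs of
  length >= 2, hence free of any quadruplex candidate;
* peak significance scores (-log10 FDR) from a two-component truncated
  Gaussian model so cassette peaks dominate the top ranks.

Ground-truth labels are written alongside, so compound-classification
sensitivity and specificity of 1.0 are forced by construction and any
deviation indicates a defect in the scanning or classification code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    GeneModel,
    Genome,
    GenomicInterval,
    write_bed6,
    write_fasta,
    write_genes_tsv,
    write_peaks_bed,
)
from .peak_annotation import PeakRecord
from .site_classifier import SiteG4Profile

#: Plus-strand quadruplex-forming unit: four 3-G runs, three 3-nt loops.
G4_UNIT = "GGGTTAGGGTTAGGGTTAGGG"
#: Its reverse complement (a minus-strand quadruplex in forward sequence).
G4_UNIT_RC = "CCCTAACCCTAACCCTAACCC"
#: Spacer between cassette units: no G/C at all, quadruplex-inert.
_SPACER = "TTATCATTATCA"
#: A concrete instance of the degenerate motif GGVGGCNGVGGHDGS.
MOTIF_INSTANCE = "GGAGGCTGCGGAAGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 50 compound cassettes, 100 single-quadruplex cassettes
    and 100 quadruplex-free background peaks (250 sites) on a 5 x 400 kb
    genome at 41% background GC, with cassette peaks scoring well above
    background (-log10 FDR 8 +/- 2 vs 1.5 +/- 0.7, truncated at 0).
    """

    seed: int = 42
    n_chroms: int = 5
    chrom_length: int = 400_000
    background_gc: float = 0.41
    n_genes: int = 160
    n_compound_cassettes: int = 50
    n_single_g4_cassettes: int = 100
    n_background_peaks: int = 100
    peak_width: int = 300
    cassette_score_mean: float = 8.0
    cassette_score_sd: float = 2.0
    background_score_mean: float = 1.5
    background_score_sd: float = 0.7
    motif_embed_rate: float = 0.8
    island_gc: float = 0.70
    island_pad: int = 150
    tss_island_fraction: float = 0.8
    slot_size: int = 6_000

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.n_genes, self.n_compound_cassettes,
            self.n_single_g4_cassettes, self.n_background_peaks,
        )
        if min(counts) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_compound_cassettes + self.n_single_g4_cassettes > self.n_genes:
            raise ValueError("more cassettes than host genes")
        if self.cassette_score_mean <= self.background_score_mean:
            raise ValueError("cassette score mean must exceed background's")
        if not (0 < self.background_gc < 1 and 0 < self.island_gc < 1):
            raise ValueError("GC fractions must be in (0, 1)")
        if not (0 <= self.motif_embed_rate <= 1 and 0 <= self.tss_island_fraction <= 1):
            raise ValueError("rates must be in [0, 1]")
        n_slots = self.n_chroms * (self.chrom_length // self.slot_size)
        if self.n_genes + self.n_background_peaks > n_slots:
            raise ValueError(
                f"infeasible placement: {self.n_genes + self.n_background_peaks}"
                f" sites but only {n_slots} genome slots"
            )
        compound_len = 3 * len(G4_UNIT) + 2 * len(_SPACER)
        if self.peak_width < compound_len + 2 * (15 + len(MOTIF_INSTANCE) + 45):
            raise ValueError("peak_width too small for cassette plus motif spacing")
        if self.slot_size < 6_000 or self.chrom_length < self.slot_size:
            raise ValueError("slot_size must be >= 6000 and fit the chromosome")


@dataclass(frozen=True)
class GroundTruthRecord:
    site_id: str
    interval: GenomicInterval
    label: str  # compound | single_g4 | background
    host_gene: str  # "." for background
    motif_embedded: bool


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    genes: list[GeneModel]
    peaks: list[PeakRecord]
    islands: list[GenomicInterval]
    truth: list[GroundTruthRecord]


def _iid_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _sterile_sample(
    rng: np.random.Generator, length: int, gc: float,
    prev: str = "", nxt: str = "",
) -> str:
    """Random sequence at target GC with no G- or C-run of length >= 2.

    Adjacent equal G/C draws are flipped to the complementary strong base,
    which preserves GC content; boundary context characters (``prev``
    before, ``nxt`` after) are honoured so no run forms across a junction
    with immutable neighbouring sequence.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=length, p=p)
    out: list[str] = []
    last = prev[-1] if prev else ""
    for d in draws:
        b = "ACGT"[d]
        if b in "GC" and b == last:
            b = "C" if b == "G" else "G"
        out.append(b)
        last = b
    if nxt and out and out[-1] in "GC" and out[-1] == nxt[0]:
        alt = "C" if out[-1] == "G" else "G"
        before = out[-2] if length > 1 else (prev[-1] if prev else "")
        out[-1] = alt if alt != before else "T"
    return "".join(out)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from N(mean, sd) conditioned on being >= 0."""
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)


def _cassette_sequence(label: str, gene_strand: str) -> str:
    """Forward-strand cassette content for a host gene of given strand.

    Compound: two template-strand units plus one non-template unit; the
    template strand is the complement of the gene's (mRNA-sense) strand.
    Single: one non-template (sense-strand) unit.
    """
    sense = G4_UNIT if gene_strand == "+" else G4_UNIT_RC
    template = G4_UNIT_RC if gene_strand == "+" else G4_UNIT
    if label == "compound":
        return template + _SPACER + template + _SPACER + sense
    return sense


def _build_footprint(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    cassette: str | None,
    embed_motif: bool,
    gc: float,
) -> str:
    """One peak footprint: immutable inserts joined by sterile flanks."""
    w = cfg.peak_width
    inserts: list[tuple[int, str]] = []
    if embed_motif:
        inserts.append((15, MOTIF_INSTANCE))
    if cassette is not None:
        inserts.append(((w - len(cassette)) // 2, cassette))
    parts: list[str] = []
    cursor = 0
    prev = ""
    for off, ins in inserts:
        flank = _sterile_sample(rng, off - cursor, gc, prev=prev, nxt=ins)
        parts.append(flank)
        parts.append(ins)
        cursor = off + len(ins)
        prev = ins
    parts.append(_sterile_sample(rng, w - cursor, gc, prev=prev))
    seq = "".join(parts)
    assert len(seq) == w
    return seq


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Build the synthetic cohort in memory; deterministic given the seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_arrays = {
        name: _iid_bases(rng, cfg.chrom_length, cfg.background_gc)
        for name in chrom_names
    }

    slots_per_chrom = cfg.chrom_length // cfg.slot_size
    all_slots = [
        (name, s * cfg.slot_size)
        for name in chrom_names
        for s in range(slots_per_chrom)
    ]
    order = rng.permutation(len(all_slots))
    gene_slots = [all_slots[i] for i in order[: cfg.n_genes]]
    bg_slots = [
        all_slots[i]
        for i in order[cfg.n_genes : cfg.n_genes + cfg.n_background_peaks]
    ]

    def paste(chrom: str, start: int, seq: str) -> None:
        arr = chrom_arrays[chrom]
        arr[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    genes: list[GeneModel] = []
    peaks: list[PeakRecord] = []
    islands: list[GenomicInterval] = []
    truth: list[GroundTruthRecord] = []
    site_counter = 0

    labels = (
        ["compound"] * cfg.n_compound_cassettes
        + ["single_g4"] * cfg.n_single_g4_cassettes
        + [None] * (cfg.n_genes - cfg.n_compound_cassettes - cfg.n_single_g4_cassettes)
    )

    for (chrom, s0), label in zip(gene_slots, labels):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = s0 + 500
            exon_spans = [(tss, tss + 400), (tss + 1000, tss + 2000), (tss + 2600, tss + 3400)]
        else:
            tss = s0 + 5500
            exon_spans = [(tss - 3400, tss - 2600), (tss - 2000, tss - 1000), (tss - 400, tss)]
        exons = tuple(GenomicInterval(chrom, a, b, strand) for a, b in exon_spans)
        gene = GeneModel(f"gene{len(genes):04d}", chrom, strand, tss, exons)
        genes.append(gene)

        # CpG-island-like block near the TSS for a fraction of genes
        if rng.random() < cfg.tss_island_fraction:
            lo, hi = tss - 100, tss + 300
            paste(chrom, lo, "".join(
                chr(b) for b in _iid_bases(rng, hi - lo, cfg.island_gc)
            ))
            islands.append(GenomicInterval(chrom, lo, hi))

        if label is None:
            continue

        # cassette peak centred on the middle exon (0-5 kb downstream of TSS)
        mid_exon = exons[1]
        center = (mid_exon.start + mid_exon.end) // 2
        fs = center - cfg.peak_width // 2
        fe = fs + cfg.peak_width
        cassette = _cassette_sequence(label, strand)
        embed = bool(rng.random() < cfg.motif_embed_rate)
        footprint = _build_footprint(rng, cfg, cassette, embed, cfg.island_gc)
        paste(chrom, fs, footprint)
        # GC-rich pads extend the island beyond the footprint
        pad_l = "".join(chr(b) for b in _iid_bases(rng, cfg.island_pad, cfg.island_gc))
        pad_r = "".join(chr(b) for b in _iid_bases(rng, cfg.island_pad, cfg.island_gc))
        paste(chrom, fs - cfg.island_pad, pad_l)
        paste(chrom, fe, pad_r)
        islands.append(GenomicInterval(chrom, fs - cfg.island_pad, fe + cfg.island_pad))

        site_id = f"site{site_counter:04d}"
        site_counter += 1
        score = _truncated_normal(rng, cfg.cassette_score_mean, cfg.cassette_score_sd)
        interval = GenomicInterval(chrom, fs, fe)
        peaks.append(PeakRecord(interval=interval, score=score, name=site_id))
        truth.append(GroundTruthRecord(site_id, interval, label, gene.name, embed))

    for chrom, s0 in bg_slots:
        fs = s0 + (cfg.slot_size - cfg.peak_width) // 2
        fe = fs + cfg.peak_width
        footprint = _build_footprint(rng, cfg, None, False, cfg.background_gc)
        paste(chrom, fs, footprint)
        site_id = f"site{site_counter:04d}"
        site_counter += 1
        score = _truncated_normal(
            rng, cfg.background_score_mean, cfg.background_score_sd
        )
        interval = GenomicInterval(chrom, fs, fe)
        peaks.append(PeakRecord(interval=interval, score=score, name=site_id))
        truth.append(GroundTruthRecord(site_id, interval, "background", ".", False))

    genome = Genome({
        name: arr.tobytes().decode("ascii") for name, arr in chrom_arrays.items()
    })
    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    return SyntheticDataset(cfg, genome, genes, peaks, islands, truth)


def write_truth_tsv(truth: list[GroundTruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tchrom\tstart\tend\tlabel\thost_gene\tmotif_embedded\n")
        for t in truth:
            fh.write(
                f"{t.site_id}\t{t.interval.chrom}\t{t.interval.start}\t"
                f"{t.interval.end}\t{t.label}\t{t.host_gene}\t{int(t.motif_embedded)}\n"
            )


def read_truth_tsv(path) -> list[GroundTruthRecord]:
    truth = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("site_id\t"):
            raise ValueError(f"{path}: missing truth TSV header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sid, chrom, start, end, label, gene, motif = line.split("\t")
            truth.append(
                GroundTruthRecord(
                    sid, GenomicInterval(chrom, int(start), int(end)),
                    label, gene, bool(int(motif)),
                )
            )
    return truth


def generate_dataset(
    config: SyntheticConfig | None = None, outdir: str | Path = "."
) -> SyntheticDataset:
    """Simulate and write genome.fa, genes.tsv, peaks.bed, islands.bed, truth.tsv."""
    ds = simulate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, outdir / "genome.fa")
    write_genes_tsv(ds.genes, outdir / "genes.tsv")
    write_peaks_bed(ds.peaks, outdir / "peaks.bed")
    write_bed6(ds.islands, outdir / "islands.bed")
    write_truth_tsv(ds.truth, outdir / "truth.tsv")
    return ds


@dataclass(frozen=True)
class ConfusionTable:
    """Predicted compound flag cross-tabulated against true labels."""

    tp: int  # true compound, predicted compound
    fn: int  # true compound, predicted non-compound
    fp: int  # true non-compound, predicted compound
    tn: int  # true non-compound, predicted non-compound
    by_label: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan


def truth_confusion(
    profiles: list[SiteG4Profile], truth: list[GroundTruthRecord]
) -> ConfusionTable:
    """Compare predicted compound flags with ground-truth labels by site id."""
    pred = {p.site_id: p.compound for p in profiles}
    truth_ids = {t.site_id for t in truth}
    if set(pred) != truth_ids:
        missing = truth_ids.symmetric_difference(pred)
        raise ValueError(f"site id mismatch between profiles and truth: {sorted(missing)[:5]}")
    tp = fn = fp = tn = 0
    by_label: dict[str, dict[str, int]] = {}
    for t in truth:
        is_pred = pred[t.site_id]
        cell = by_label.setdefault(t.label, {"compound": 0, "non_compound": 0})
        cell["compound" if is_pred else "non_compound"] += 1
        if t.label == "compound":
            tp += is_pred
            fn += not is_pred
        else:
            fp += is_pred
            tn += not is_pred
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, by_label=by_label)
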