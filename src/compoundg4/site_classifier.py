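"""Compound-G4 site classification.

A site is *compound* when predicted quadruplexes occur on both DNA strands
and at least one strand carries two or more.  Both component flags (any-G4,
both-strands, compound) are retained per site so either marginal statistic
can be reported for a cohort.  When a host gene is supplied the strand
counts can be re-expressed as template / non-template relative to the
gene's orientation (template = the strand complementary to the mRNA sense).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genome_io import Genome, GeneModel, GenomicInterval, extract_sequence
from .g4_engine import G4Hit, G4Params, find_g4


@dataclass(frozen=True)
class SiteG4Profile:
    """Per-site strandwise quadruplex counts and classification flags."""

    site_id: str
    interval: GenomicInterval
    n_plus: int
    n_minus: int
    tetrad_histogram: dict[int, int] = field(default_factory=dict)
    hits: tuple[G4Hit, ...] = ()
    n_template: int | None = None
    n_nontemplate: int | None = None

    @property
    def n_total(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def any_g4(self) -> bool:
        return self.n_total >= 1

    @property
    def both_strands(self) -> bool:
        return self.n_plus >= 1 and self.n_minus >= 1

    @property
    def two_on_one_strand(self) -> bool:
        return max(self.n_plus, self.n_minus) >= 2

    @property
    def compound(self) -> bool:
        return self.both_strands and self.two_on_one_strand


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level fractions over sites, plus the two-tetrad hit fraction."""

    n_sites: int
    frac_any_g4: float
    frac_both_strands: float
    frac_compound: float
    frac_two_tetrad_hits: float
    n_hits: int

    def __post_init__(self) -> None:
        if not (
            self.frac_compound <= self.frac_both_strands <= self.frac_any_g4 + 1e-12
        ):
            raise ValueError("compound <= both_strands <= any_g4 violated")


def classify_site(
    genome: Genome,
    interval: GenomicInterval,
    params: G4Params | None = None,
    site_id: str | None = None,
    gene: GeneModel | None = None,
    select: bool = True,
    flank: int = 0,
) -> SiteG4Profile:
    """Profile the quadruplexes under one site.

    The plus-strand sequence of ``interval`` (optionally padded by ``flank``
    bp on each side) is scanned on both strands with :func:`find_g4`.  When
    a flank is used, a hit counts toward the site iff its midpoint lies
    inside the unpadded interval, making counts deterministic for
    boundary-straddling hits.  ``select=False`` counts raw candidates
    instead of the non-overlapping selection.  With ``gene`` provided, the
    strandwise counts are also expressed as template / non-template
    (template = opposite of the gene's strand).
    """
    if params is None:
        params = G4Params()
    chrom_len = genome.chrom_length(interval.chrom)
    lo = max(0, interval.start - flank)
    hi = min(chrom_len, interval.end + flank)
    scan_iv = GenomicInterval(interval.chrom, lo, hi, "+")
    seq = extract_sequence(genome, scan_iv)
    hits = find_g4(seq, params, both_strands=True, select=select)

    kept: list[G4Hit] = []
    for h in hits:
        mid = lo + (h.interval.start + h.interval.end) // 2
        if interval.start <= mid < interval.end:
            kept.append(
                G4Hit(
                    interval=GenomicInterval(
                        interval.chrom,
                        lo + h.interval.start,
                        lo + h.interval.end,
                        h.interval.strand,
                    ),
                    tetrads=h.tetrads,
                    loops=h.loops,
                    gscore=h.gscore,
                )
            )
    n_plus = sum(1 for h in kept if h.interval.strand == "+")
    n_minus = len(kept) - n_plus
    histo: dict[int, int] = {}
    for h in kept:
        histo[h.tetrads] = histo.get(h.tetrads, 0) + 1

    n_template = n_nontemplate = None
    if gene is not None:
        # non-template = mRNA-sense strand = the gene's strand
        if gene.strand == "+":
            n_nontemplate, n_template = n_plus, n_minus
        else:
            n_nontemplate, n_template = n_minus, n_plus

    return SiteG4Profile(
        site_id=site_id or f"{interval.chrom}:{interval.start}-{interval.end}",
        interval=interval,
        n_plus=n_plus,
        n_minus=n_minus,
        tetrad_histogram=histo,
        hits=tuple(kept),
        n_template=n_template,
        n_nontemplate=n_nontemplate,
    )


def summarize_cohort(profiles: list[SiteG4Profile]) -> CohortSummary:
    """Fractions over sites; the two-tetrad fraction pools hits across sites."""
    if not profiles:
        raise ValueError("cannot summarize an empty cohort")
    n = len(profiles)
    n_hits = sum(p.n_total for p in profiles)
    n_g2 = sum(p.tetrad_histogram.get(2, 0) for p in profiles)
    return CohortSummary(
        n_sites=n,
        frac_any_g4=sum(p.any_g4 for p in profiles) / n,
        frac_both_strands=sum(p.both_strands for p in profiles) / n,
        frac_compound=sum(p.compound for p in profiles) / n,
        frac_two_tetrad_hits=(n_g2 / n_hits) if n_hits else math.nan,
        n_hits=n_hits,
    )


def profiles_to_tsv(profiles: list[SiteG4Profile], path) -> None:
    """Per-site table: id, coordinates, strand counts, flags, tetrad classes."""
    with open(path, "w") as fh:
        fh.write(
            "site_id\tchrom\tstart\tend\tn_plus\tn_minus\t"
            "both_strands\tcompound\tn_g2\tn_g3plus\n"
        )
        for p in profiles:
            n_g2 = p.tetrad_histogram.get(2, 0)
            n_g3 = p.n_total - n_g2
            fh.write(
                f"{p.site_id}\t{p.interval.chrom}\t{p.interval.start}\t"
                f"{p.interval.end}\t{p.n_plus}\t{p.n_minus}\t"
                f"{int(p.both_strands)}\t{int(p.compound)}\t{n_g2}\t{n_g3}\n"
            )
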