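"""Quadruplex-forming sequence enumeration, scoring and selection.

A candidate quadruplex is four equal-length G-runs (each ``g`` consecutive
guanines, ``g`` tetrads when folded) separated by three loops of bounded
length, the whole within a maximum span.  Runs may be sub-runs of longer
G-tracts, so enumeration is complete over all placements.  Candidates are
scored with a linear G-score favouring more tetrads, shorter spans and
balanced loops, then reduced to a non-overlapping hit set per strand by
greedy selection on descending score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomicInterval, reverse_complement


@dataclass(frozen=True)
class G4Params:
    """Enumeration bounds and G-score weights.

    min_tetrads
        Smallest tetrad count considered (default 2: two stacked tetrads is
        the minimal quadruplex).
    max_tetrads
        Cap on tetrad count (default 6); longer tracts contribute sub-runs.
    max_span : bp
        Maximum end-to-start extent of a candidate (default 45).
    min_loop, max_loop : bp
        Loop length bounds (defaults 1 and 36; zero-length loops excluded).
    c1, c2, c3
        Score weights: tetrad bonus, span slack, loop-imbalance penalty.
    """

    min_tetrads: int = 2
    max_tetrads: int = 6
    max_span: int = 45
    min_loop: int = 1
    max_loop: int = 36
    c1: float = 20.0
    c2: float = 1.0
    c3: float = 1.0

    def __post_init__(self) -> None:
        if self.min_tetrads < 2:
            raise ValueError("min_tetrads must be >= 2")
        if self.max_tetrads < self.min_tetrads:
            raise ValueError("max_tetrads < min_tetrads")
        if self.max_span < 4 * self.min_tetrads + 3 * self.min_loop:
            raise ValueError("max_span too small for four runs plus loops")
        if self.min_loop < 0 or self.max_loop < self.min_loop:
            raise ValueError("require 0 <= min_loop <= max_loop")
        if min(self.c1, self.c2, self.c3) < 0:
            raise ValueError("score weights must be >= 0")


@dataclass(frozen=True)
class G4Candidate:
    """One placement of four g-length G-runs; plus-strand local coordinates."""

    run_starts: tuple[int, int, int, int]
    tetrads: int
    loops: tuple[int, int, int]
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.run_starts[0]

    @property
    def end(self) -> int:
        return self.run_starts[3] + self.tetrads

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class G4Hit:
    """A selected quadruplex with its interval, tetrad count and G-score."""

    interval: GenomicInterval
    tetrads: int
    loops: tuple[int, int, int]
    gscore: float


def gscore(candidate: G4Candidate, params: G4Params | None = None) -> float:
    """Linear G-score: c1*(g - g_min) + c2*(max_span - span) - c3*loop_imbalance.

    Higher for more tetrads, shorter span and more balanced loops; the loop
    imbalance is max(loop) - min(loop).
    """
    if params is None:
        params = G4Params()
    imbalance = max(candidate.loops) - min(candidate.loops)
    return (
        params.c1 * (candidate.tetrads - params.min_tetrads)
        + params.c2 * (params.max_span - candidate.span)
        - params.c3 * imbalance
    )


def _g_run_starts(seq: str, g: int) -> list[int]:
    """Start positions of every (sub-)run of exactly g consecutive Gs."""
    starts = []
    n = len(seq)
    run = 0
    for i, base in enumerate(seq):
        run = run + 1 if base == "G" else 0
        if run >= g:
            starts.append(i - g + 1)
    return starts


def enumerate_g4_candidates(
    seq: str, params: G4Params | None = None
) -> list[G4Candidate]:
    """All candidates on the plus strand of ``seq``, complete by construction.

    For each tetrad count g in [min_tetrads, max_tetrads] every ordered
    placement of four g-length G-runs with loops in [min_loop, max_loop] and
    span <= max_span is emitted.  N never occurs inside a run (it is not G)
    and candidates whose loops contain N are excluded.
    """
    if params is None:
        params = G4Params()
    seq = seq.upper()
    n = len(seq)
    out: list[G4Candidate] = []
    # positions of N, to veto loops over unknown bases
    n_positions = [i for i, b in enumerate(seq) if b == "N"]

    def span_has_n(lo: int, hi: int) -> bool:
        # any N in [lo, hi)?  n_positions is sorted; linear scan is fine at
        # the densities seen in practice
        for p in n_positions:
            if p >= hi:
                return False
            if p >= lo:
                return True
        return False

    for g in range(params.min_tetrads, params.max_tetrads + 1):
        starts = _g_run_starts(seq, g)
        if len(starts) < 4:
            continue
        m = len(starts)
        max_span = params.max_span
        for a in range(m):
            s1 = starts[a]
            limit = s1 + max_span
            for b in range(a + 1, m):
                s2 = starts[b]
                l1 = s2 - (s1 + g)
                if l1 < params.min_loop:
                    continue
                if l1 > params.max_loop or s2 + g > limit:
                    break
                for c in range(b + 1, m):
                    s3 = starts[c]
                    l2 = s3 - (s2 + g)
                    if l2 < params.min_loop:
                        continue
                    if l2 > params.max_loop or s3 + g > limit:
                        break
                    for d in range(c + 1, m):
                        s4 = starts[d]
                        l3 = s4 - (s3 + g)
                        if l3 < params.min_loop:
                            continue
                        if l3 > params.max_loop or s4 + g > limit:
                            break
                        if n_positions and span_has_n(s1, s4 + g):
                            continue
                        out.append(
                            G4Candidate(
                                run_starts=(s1, s2, s3, s4),
                                tetrads=g,
                                loops=(l1, l2, l3),
                            )
                        )
    return out


def select_nonoverlapping(
    candidates: list[G4Candidate], params: G4Params | None = None
) -> list[G4Hit]:
    """Greedy selection by descending G-score; kept hits never share a base.

    Ties are broken by smaller start, then smaller span.  Returned hits are
    sorted by start and carry placeholder chromosome 'seq' in local
    coordinates; callers re-map to genomic coordinates.
    """
    if params is None:
        params = G4Params()
    scored = sorted(
        candidates,
        key=lambda c: (-gscore(c, params), c.start, c.span),
    )
    kept: list[G4Candidate] = []
    occupied: list[tuple[int, int]] = []
    for cand in scored:
        lo, hi = cand.start, cand.end
        if any(lo < e and s < hi for s, e in occupied):
            continue
        kept.append(cand)
        occupied.append((lo, hi))
    kept.sort(key=lambda c: c.start)
    return [
        G4Hit(
            interval=GenomicInterval("seq", c.start, c.end, c.strand),
            tetrads=c.tetrads,
            loops=c.loops,
            gscore=gscore(c, params),
        )
        for c in kept
    ]


def find_g4(
    seq: str,
    params: G4Params | None = None,
    both_strands: bool = True,
    select: bool = True,
) -> list[G4Hit]:
    """Predict quadruplexes on one or both strands of ``seq``.

    Plus-strand hits come from enumerate -> score -> select on ``seq``
    itself; minus-strand hits from the same pipeline on the reverse
    complement, mapped back to forward coordinates.  Selection is per-strand
    independent.  With ``select=False`` every candidate is reported as a hit
    (raw mode).
    """
    if params is None:
        params = G4Params()
    seq = seq.upper()
    n = len(seq)

    def one_strand(s: str, strand: str) -> list[G4Hit]:
        cands = enumerate_g4_candidates(s, params)
        if select:
            hits = select_nonoverlapping(cands, params)
        else:
            hits = [
                G4Hit(
                    interval=GenomicInterval("seq", c.start, c.end, "+"),
                    tetrads=c.tetrads,
                    loops=c.loops,
                    gscore=gscore(c, params),
                )
                for c in sorted(cands, key=lambda c: (c.start, c.span))
            ]
        if strand == "-":
            hits = [
                G4Hit(
                    interval=GenomicInterval(
                        "seq", n - h.interval.end, n - h.interval.start, "-"
                    ),
                    tetrads=h.tetrads,
                    loops=h.loops,
                    gscore=h.gscore,
                )
                for h in hits
            ]
            hits.sort(key=lambda h: h.interval.start)
        else:
            hits = [
                G4Hit(
                    interval=GenomicInterval(
                        "seq", h.interval.start, h.interval.end, "+"
                    ),
                    tetrads=h.tetrads,
                    loops=h.loops,
                    gscore=h.gscore,
                )
                for h in hits
            ]
        return hits

    hits = one_strand(seq, "+")
    if both_strands:
        hits += one_strand(reverse_complement(seq), "-")
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def hits_to_bed6_rows(hits: list[G4Hit], chrom: str, offset: int = 0):
    """BED6 rows (chrom, start, end, name=g{tetrads}, score, strand)."""
    return [
        (
            chrom,
            h.interval.start + offset,
            h.interval.end + offset,
            f"g{h.tetrads}",
            h.gscore,
            h.interval.strand,
        )
        for h in hits
    ]
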