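# compoundg4

Strand-aware G-quadruplex (G4) prediction and **compound-G4** classification
of chromatin-association peaks.

Proximity-labelling and ChIP-style experiments yield ranked genomic peaks
where a protein associates with chromatin. For chromatin factors that bind
four-stranded G-quadruplex DNA, a recurring question is not just *whether* a
peak contains a predicted quadruplex but *how the quadruplexes are arranged
across the two DNA strands*: transcribed exons can carry tandem quadruplexes
on the template strand opposed by another on the non-template strand. This
package operationalises that configuration — a **compound G4 site** — and
provides the full annotation pipeline around it for anyone analysing peak
cohorts over GC-rich, transcribed sequence: quadruplex prediction, per-site
classification, and cohort statistics (GC, CpG islands, TSS distance, motif
density), plus a fully labelled synthetic genome so every stage is testable
without external downloads.

## The model

A **candidate quadruplex** on a strand is four equal-length runs of `g ≥ 2`
consecutive guanines (one run per tetrad column) separated by three loops of
1–36 nt, the whole spanning at most 45 bp. Runs may be sub-runs of longer
G-tracts, so enumeration is complete over all placements. Each candidate is
scored with a linear G-score encoding the usual preferences (more tetrads,
compact span, balanced loops):

```
gscore = c1·(g − g_min) + c2·(max_span − span) − c3·(max loop − min loop)
```

with defaults `c1 = 20, c2 = c3 = 1, g_min = 2, max_span = 45`. Per strand,
candidates are reduced to a non-overlapping hit set greedily by descending
score (ties: smaller start, then smaller span). The minus strand is scanned
as the reverse complement and mapped back to forward coordinates.

A site (peak) is then profiled by its strandwise hit counts
`(n₊, n₋)` and classified:

* **any-G4** — `n₊ + n₋ ≥ 1`;
* **both-strands** — `n₊ ≥ 1` and `n₋ ≥ 1`;
* **compound** — both strands *and* `max(n₊, n₋) ≥ 2`.

When a host gene is given, counts are re-expressed as template /
non-template (template = complement of the mRNA-sense strand).

Cohort annotation follows the standard shapes: top-*n* vs bottom-*n* GC
content by two-sided Wilcoxon rank-sum, CpG-island overlap (half-open
interval intersection; islands callable from sequence with a
Gardiner-Garden & Frommer-style sliding-window detector), a signed
distance-to-nearest-TSS histogram (downstream positive, strand-aware), and
IUPAC-motif density in peaks versus background with a pseudocounted fold
and one-sided binomial test.

## Worked example

Build the canonical compound arrangement — two template-strand quadruplexes
plus one non-template quadruplex, as found in a ribosomal-protein exon —
and classify it:

```python
from compoundg4 import Genome, GenomicInterval, classify_site, reverse_complement

g4 = "GGGTTAGGGTTAGGGTTAGGG"          # four G-runs of 3, three 3-nt loops
site = (reverse_complement(g4) + "TTATCATTATCA"
        + reverse_complement(g4) + "TTATCATTATCA" + g4)
genome = Genome({"chr1": site})
profile = classify_site(genome, GenomicInterval("chr1", 0, len(site)))
print(f"hits: +{profile.n_plus} / -{profile.n_minus}")
print(f"both strands: {profile.both_strands}, compound: {profile.compound}")
for h in profile.hits:
    print(h.interval.start, h.interval.end, h.interval.strand,
          f"g={h.tetrads}", f"score={h.gscore}")
```

prints

```
hits: +1 / -2
both strands: True, compound: True
0 21 - g=3 score=44.0
33 54 - g=3 score=44.0
66 87 + g=3 score=44.0
```

Two minus-strand hits and one plus-strand hit (each three tetrads, loops
3/3/3, G-score 44): quadruplexes on both strands with two on one strand,
hence a compound site.

The same analysis runs from the shell over a whole cohort:

```bash
compoundg4 simulate --seed 42 --out sim/        # synthetic genome + peaks + truth
compoundg4 classify --genome sim/genome.fa --peaks sim/peaks.bed --out sites.tsv
compoundg4 annotate --genome sim/genome.fa --peaks sim/peaks.bed \
    --genes sim/genes.tsv --islands sim/islands.bed --out report.json
```

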