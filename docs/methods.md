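# Methods

## Quadruplex model

A candidate quadruplex on a strand is a placement of four G-runs of equal
length `g` (the tetrad count) separated by three loops. Enumeration is
exhaustive for each `g` in `[min_tetrads, max_tetrads]`: every position at
which `g` consecutive guanines occur is a legal run start, so a G-tract of
length `L` contributes sub-runs at every offset with every `g ≤ L`. A
placement is a candidate when the loops lie in `[min_loop, max_loop]`, the
span (first run start to last run end) is at most `max_span`, and no `N`
occurs inside the span — structure is never asserted over unknown bases.
Completeness of the windowed enumerator is checked in the test suite
against an independent brute-force enumerator that tries all four-run
combinations.

Defaults: `min_tetrads = 2` (two stacked tetrads is the minimal
quadruplex, and two-tetrad structures are the class of particular interest
at compound sites), `max_tetrads = 6` (longer tracts add sub-runs, not new
structural classes, and uncapped `g` inflates the candidate set),
`max_span = 45` bp, loops 1–36 nt (zero-length loops excluded). All are
fields of `G4Params`.

### G-score

`gscore = c1·(g − g_min) + c2·(max_span − span) − c3·(max(loops) − min(loops))`
with `c1 = 20`, `c2 = c3 = 1`. The linear form encodes the standard
preferences — more tetrads dominate (the `c1` weight exceeds the largest
possible span slack contribution per extra tetrad), compact spans beat
loose ones, balanced loops beat skewed ones — while remaining exactly
testable; the weights are configuration, not constants. The score is not a
thermodynamic stability estimate.

### Selection

Per strand, hits are chosen greedily by descending score; a candidate is
kept iff it shares no base with an already-kept hit. Ties break by smaller
start, then smaller span, making the output order-independent and
deterministic. Minus-strand hits are computed on the reverse complement
and mirrored back (`start' = L − end`), so strand duality is an exact
invariant rather than an approximation. Raw mode (no selection) is exposed
because cohort statistics can legitimately be defined over either all
candidates or the non-overlapping set; the package defaults to selected
hits, which is what "one quadruplex per locus" reporting implies.

## Site classification

A site's plus-strand sequence is scanned on both strands. With a flank,
hits are attributed to the site iff their midpoint lies inside the
unpadded interval — a single unambiguous point makes boundary-straddling
hits deterministic. Flags: `any_g4` (≥1 hit), `both_strands` (≥1 per
strand), `compound` (= both strands AND ≥2 on at least one strand). The
two component flags are kept separate so either marginal can be reported
on a cohort; `compound ⇒ both_strands ⇒ any_g4` is enforced as a type
invariant. Template/non-template counts are defined only relative to a
supplied gene: the non-template strand is the gene's (mRNA-sense) strand.

## CpG islands

Sliding 200-bp windows (stride 1) pass when GC > 0.5 and observed/expected
CpG > 0.6, with obs/exp = `#CG·window / (#C·#G)` and `#C·#G > 0`
(Gardiner-Garden & Frommer-style thresholds; the comparisons are strict,
matching the classical ">50%" phrasing). Passing windows are merged;
each merged segment is then trimmed so it starts and ends on a strong base
and shrunk until the segment as a whole passes both thresholds, then
dropped if shorter than `min_length` (200 bp). Without the whole-segment
re-check, windows straddling a flank at exactly threshold GC drag A/T
sequence into the island; the trim makes a flanked CG run resolve to
exactly the run, and a sub-200-bp run to nothing. The caller is a
configurable stand-in for pre-computed genome-browser CpG tracks, which
use related but not identical rules.

## Peak annotation

* **Ranking** — descending −log10 FDR, ties by (chrom, start); rank 1 is
  most significant.
* **GC comparison** — two-sided Wilcoxon rank-sum on per-peak GC of the
  top-*n* versus bottom-*n* ranked peaks. Rank-sum rather than a t-test
  because GC fractions are bounded and skewed; the statistic is the
  large-sample normal approximation, which returns p = 1 for identical
  groups and stays defined at n = 1. N bases are excluded from the GC
  denominator.
* **CpG overlap** — fraction of peaks sharing ≥1 bp with any island,
  half-open, so abutting intervals do not overlap; islands are merged
  internally, making the fraction invariant to island fragmentation.
* **TSS distance** — signed distance from peak midpoint to the nearest
  same-chromosome TSS, sign flipped for minus-strand genes so downstream
  is positive; binned at ±5/50/500 kb by default with open outer bins and
  an explicit unassigned bucket. This deliberately replaces basal-plus-
  extension gene-regulatory-domain rules with the simplest annotation
  that produces the same histogram shape.
* **Motif density** — occurrences of an IUPAC motif (overlaps counted,
  both strands, minus-strand matches reported in forward coordinates) per
  kb in peaks versus a background peak set. Fold uses a pseudocount of one
  occurrence over the combined bp so motif-free backgrounds give finite
  folds; the one-sided binomial test uses the background per-position
  match rate as the null. An `N` in the sequence matches only the motif
  code `N`. Motif *discovery* is out of scope; scanning a given motif is
  not.

## Synthetic data generator

The generator emulates the statistical structure of a chromatin-
association cohort over transcribed GC-rich sequence; its defaults are the
package's study conditions: 5 × 400 kb chromosomes of i.i.d. sequence at
41% GC (mammalian-like background), 160 genes with TSSs and three exons
within 5 kb downstream, 50 compound cassettes and 100 single-quadruplex
cassettes centred in middle exons, 100 background peaks, 300-bp peaks,
and scores from two truncated Gaussians (8 ± 2 cassette, 1.5 ± 0.7
background, −log10 FDR scale) so cassette peaks dominate the top ranks.

Construction guarantees, which turn recovery tests into exact checks:

* Cassettes are built from a telomeric-type unit (four 3-G runs, 3-nt
  loops): compound = two template-strand units + one non-template unit;
  single = one non-template unit. Template is defined by the host gene's
  strand. Unit spacing ensures cross-unit candidates always lose the
  greedy selection to the per-unit hits, so compound cassettes classify
  with exactly (2, 1) strandwise hits and singles with exactly one.
* Every peak footprint outside embedded cassettes/motifs is sampled with
  no G- or C-run of length ≥ 2 (adjacent identical strong bases are
  flipped to the complementary strong base, preserving GC; junctions with
  immutable inserts are boundary-checked). Four runs are necessary for any
  candidate, so background footprints are quadruplex-free by construction
  and specificity 1.0 is forced unless the scanner is defective.
* GC-rich (70%) CpG-island-like blocks cover every cassette footprint
  (±150 bp) and sit at 80% of TSSs, driving the top-vs-bottom GC and
  CpG-overlap contrasts; a concrete instance of the degenerate motif
  GGVGGCNGVGGHDGS is embedded in 80% of cassette footprints, ≥45 bp from
  any cassette unit so it can never complete a spurious candidate (its
  three G-runs are one short of a quadruplex).
* All randomness flows through one seeded generator in a fixed order;
  outputs are byte-identical across runs.

What the generator does **not** emulate: read-level coverage, alignment
artefacts, FDR estimation, overlapping genes, repeat families, chromatin
domain structure, or quadruplexes with non-canonical loop compositions.
Passing recovery tests therefore demonstrates the correctness of the
scanning/classification machinery under the declared model, not
performance on real peak calls, where boundary effects and ambiguous
sequence will blur the exact counts.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open throughout (BED convention).
* GC of an all-N sequence is NaN (undefined marker); empty sequences are
  errors, not zeros. NaN fractions serialize as JSON null.
* An empty peak file yields a successful run with `n_sites = 0` and null
  cohort fields; an empty cohort passed to the summariser is an error.
* Report JSON uses fixed key order and 6-decimal float rounding so
  re-runs are byte-diffable.
* Sensitivity/specificity are NaN when their denominator class is absent.

## Problem sizes

The test suite verifies enumerator completeness on 500 random 80-nt and
100 random 200-nt sequences against the brute-force oracle, strand duality
on 500 sequences, rank-sum calibration over 200 replicates of a 200-peak
null cohort, and motif density against the closed-form match probability
on 3–4 Mb of i.i.d. background; the full suite runs in well under a
minute. The acceptance script uses the default 250-peak cohort.

## Known limitations

The G-score is a declared linear surrogate, not a fit to folding
energies; candidate enumeration treats strands independently and ignores
competition between overlapping plus- and minus-strand structures; the
CpG caller approximates, but does not reproduce, browser-track islands;
nearest-TSS annotation ignores gene extent and expression; the compound
criterion is purely computational and carries no claim about in vitro
folding of any particular site.
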