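# Methods

## Model and assumptions

`dropsketch` quantifies droplet scRNA-seq data under three assumptions:

1. **Reads are contiguous substrings of one transcript** (no splicing
   within a read — the reference is a transcriptome, not a genome).
   This justifies range accumulation: true feature hits fall in
   adjacent reference windows, spurious hits scatter.
2. **Cell barcodes and UMIs are positional**: mate 1 is CB (16 nt)
   followed by UMI (10 nt); extraction never realigns. Consequently
   only substitution errors in mate 1 are modelled or corrected.
3. **Sequencing error in a UMI is rarer than the molecule it tags**,
   the premise of the directional deduplication criterion.

## Sketching geometry

A sequence of length L is cut into m = ⌊(L − k)/t⌋ + 1 windows, window
i spanning [i·t, min(i·t + w, L)). With the default stride
t = w − k + 1, every k-mer start position belongs to exactly one stride
bin and the spans jointly cover the sequence, so no k-mer is ever
skipped and none is double-counted within one window layout.

A window's sketch is the s smallest distinct values of h1 over its
canonical k-mers. h1 is the splitmix64 finalizer applied to the 2-bit
packed code min(kmer, revcomp(kmer)); it is fixed (not salted) so
databases and results are bit-reproducible. k-mers containing non-ACGT
characters are skipped deterministically. Canonicalization makes the
sketch strand-symmetric, which handles the ~50% of 10x cDNA reads that
are antisense to their transcript without a second lookup pass.

Defaults (units: bases unless stated): k = 16, s = 16,
w = ⌊(R + k − 1)/2⌋ (56 for read length R = 98), t = w − k + 1 = 41.
The accumulation range r = ⌊(R − k − 1)/t⌋ + 2 (= 3 for the defaults)
is the smallest window count that never splits a contiguously aligned
read's hits across range boundaries: the read's R − k + 1 k-mer starts
span at most that many stride bins. A 98-base read yields windows with
sketch capacities 16 + 16 + 1 = 33 features; the default score
threshold 28 is ~85% of that maximum. The threshold is applied
inclusively (score ≥ threshold): with integer scores and a guidance of
"about 80% of maximum", 28-of-33 inclusive tracks the intent better
than strict 29-of-33.

Features stored at more than `max_locations` = 1000 locations are
deleted outright rather than truncated: truncation would bias toward
transcripts early in input order, and such promiscuous features carry
almost no discriminative signal anyway.

## Whitelisting

Inclusive prefix sum with a strict `<` cutoff over counts sorted
descending (ties lexicographic, making the result independent of input
order). Note a structural consequence: the last-ranked barcode's
inclusive prefix equals the total, so it can never be admitted for any
fraction ≤ 1 — on real data that barcode is part of the error tail by
construction, but on error-free synthetic data it is a real cell. Tests
that require *all* true cells therefore supply the known barcode list
through the pipeline's `use_whitelist` path, and whitelist behaviour is
tested separately under an error model where a knee exists.

Rescue: a non-member CB is assigned to the unique whitelist member
within edit distance one (Levenshtein via edlib; for fixed-length
16-mers this coincides with Hamming distance one, and a
substitutions-only mode is exposed as `hamming_only`). Multiple
candidates are resolved by strictly highest whitelist count, else the
read is discarded — frequency is the natural prior and a wrong
assignment is worse than a lost read.

## Mapping score

Each feature occurrence in each read window contributes one hit to
every stored location of that feature; a feature value appearing in
two read windows counts twice. The score of a transcript is the
maximum over window-range starts of the sum of hits in r consecutive
reference windows (absent windows count zero; an optimal range can
always start at a hit window). Candidates are transcripts with score ≥
threshold; a read is kept only when all candidates share one gene, and
its gene score is the maximum candidate score. Reads shorter than k
are malformed by definition (no features exist).

Discard precedence: malformed → barcode-unmatched → unmapped →
ambiguous-gene. All discards are typed and tallied in
`run_summary.json`.

## Deduplication

Per (cell, gene) group: directed edge A→B iff Hamming(A,B) = 1 and
count(A) ≥ factor·count(B) − 1 (factor default 2, the directional
criterion of UMI-tools). UMIs are visited in descending count order
(ties lexicographic); each unvisited UMI seeds a breadth-first
expansion and the number of expansions is the molecule count. Grouping
is strictly per (cell, gene): the same UMI string under two genes in
one cell counts as two molecules, since cross-gene collapse would
require an arbitration rule with no principled basis here.

One boundary worth noting: when count(B) = 1 the edge threshold is
factor − 1, so even factor = max-count + 1 can still admit an edge
from a maximal UMI; only factor ≥ max-count + 2 forbids all edges.

## Synthetic data

The generator emulates the Chromium v2 layout end to end: multi-isoform
genes (isoforms share a 60% prefix), optional gene pairs embedding one
verbatim ≥150-base block to provoke cross-gene ambiguity, a true CB set
with pairwise Hamming distance ≥ 3, per-molecule UMIs, PCR duplication,
independent per-base substitution errors for CB/UMI/cDNA, and antisense
reads with probability ½. Baseline conditions: 20 genes × 2 isoforms
(lengths 400–800), 50 cells, Poisson(20) molecules per (cell, gene)
(~20k reads), R = 98, all error and duplication rates zero unless a
study turns them on.

Three deliberate conventions make exact accounting possible:

- **Molecule starts lie on the stride grid** (multiples of t) by
  default. A window-aligned error-free read reproduces reference
  window sketches verbatim, guaranteeing a score floor of 2s = 32 ≥ 28;
  arbitrary offsets (available via `window_aligned=False`) give
  partial sketch overlap and no such guarantee.
- **UMIs within one (cell, gene) group are distinct with pairwise
  Hamming ≥ 2.** With singleton counts the directional rule merges
  *any* distance-1 pair, so random distance-1 collisions (a handful
  expected across 1000 groups) would silently undercount molecules;
  the exactness claims presume distinguishable true molecules, and
  UMI *errors* (which create the collapsible distance-1 shadows) are
  modelled separately.
- **Reads per molecule = 1 + Binomial(4, pcr_rate)** — a bounded
  duplicate model; at pcr_rate 0.5 the mean is 3 reads/molecule.

What passing these tests does *not* show about real data: realistic
expression distributions, ambient RNA/empty droplets, doublets, indel
errors, quality-score structure, and non-window-aligned coverage are
all outside the generator; recovery rates on real libraries will be
lower and whitelist behaviour depends on the real knee shape.

## Numerical and design choices

- Hashes are uint64 with wrapping arithmetic (numpy); sketches are
  ascending and deduplicated; all positions 0-based half-open.
- The database serializes to gzipped JSON with a format/version tag;
  gzip headers are normalized (mtime 0, no filename) so
  save(load(x)) = x and repeated saves are byte-identical.
- Matrix rows are cells sorted lexicographically by barcode — a
  deliberate determinism choice replacing thread-order-dependent row
  output; columns follow taxonomy gene order, zero-count genes keep
  their column.
- Parallelism is batch-based behind a determinism contract: batches
  are mapped on a thread pool and merged in submission order, so any
  thread count and batch size give byte-identical outputs. Stages are
  strictly barriered (whitelist, then mapping, then dedup).
- Problem sizes in the test and acceptance runs (≤100-transcript
  references for oracle comparisons, ~20k-read simulations for
  recovery studies) are the package's chosen study scale: large enough
  that every pipeline stage is exercised with thousands of decisions,
  small enough to iterate on.

## Known limitations

- Transcript-level quantification is out of scope; multi-gene reads
  are discarded rather than fractionally assigned.
- The whitelist prefix-sum rule is a heuristic, not a cell caller; no
  knee detection or EM is attempted, and the last-ranked barcode
  exclusion noted above is inherent to the rule.
- Short transcripts (< k) contribute nothing to the database; short
  reads (< k) are discarded as malformed.
- Mapping is exact-hash based: a single substitution inside a window
  changes up to k of its k-mers and can remove sketch members, so
  error tolerance comes from the threshold margin (28 of 33), not from
  inexact matching.
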