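# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (BED convention) internally; GTF is
converted from 1-based inclusive on read and back on write. "Overlap"
means ≥ 1 bp shared, so bookended intervals do not overlap — this matches
`bedtools intersect` and makes every boundary deterministic. The interval
operations mirror the bedtools commands they replace:

* `window_join(A, B, w)` = `bedtools window -w`: a is padded by ±w and
  intersected with B. A gap of exactly w does **not** pair (half-open
  padding); w = 0 reduces to a plain intersect.
* `stitch(A, d)` = `bedtools merge -d`: the gap between consecutive sorted
  intervals is `start_next − end_prev`; gap ≤ d merges, so d = 0 merges
  bookended intervals. Stitching is idempotent and its constituents
  partition the input.
* `exclude_overlapping(A, B, pad)` = `bedtools intersect -v` against a
  padded B.
* `closest_features` reports, per query, all overlapping features
  (distance 0) plus the nearest feature per direction with a signed
  edge-to-edge distance (negative toward lower coordinates). Ties go to
  the lower-coordinate feature — the data formats carry no information
  that could break ties more meaningfully, and a deterministic rule is
  required for reproducible output. Reporting the nearest feature *per
  direction* (rather than one signed closest) is deliberate: target
  assignment wants candidates on both flanks.

Padding clips at zero; there is no chromosome-length clipping unless a
length is known (the eRNA locus window is clipped only at the chromosome
start for the same reason).

Overlap queries are backed by per-chromosome interval trees
(`intervaltree`); the semantics above are defined in this package and
verified exactly against O(n²) brute-force oracles in the test suite.

## Peak-quality filter

narrowPeak records are kept when fold enrichment is strictly above 4 and
the q-value strictly below 0.05. The comparison is done in −log10 space
(`neg_log10_q > −log10(0.05)`) to avoid underflow on extreme q-values;
records carrying the −1 missing-value sentinel are dropped and counted in
a warning rather than silently passed.

## Peak annotation

The peak midpoint determines the category — midpoint assignment emulates
summit-centric annotators, is order-independent, and gives exactly one
category per peak. Precedence: promoter (TSS to 2.5 kb upstream of a
protein-coding gene, strand-aware, endpoints inclusive) > intragenic
(protein-coding gene body; introns, exons and UTRs are collapsed) > other
(body or promoter window of a pseudogene/miRNA/small-RNA gene) >
intergenic. When the midpoint satisfies a rule for several genes, the gene
with the nearest TSS wins, with remaining ties to the lower coordinate.
"Target genes" are genes receiving at least one promoter or gene-body
peak; intergenic peaks do not create targets. Whether nearest-gene
assignment of intergenic peaks should also count is genuinely open; the
stricter definition is used because it is insensitive to gene-desert
geometry, and the distance cap that would make nearest-gene assignment
well-behaved is already the job of the SE target-assignment step.

## Signal and RPKM

Region signal is the area under a stepwise coverage track, scaled to
reads-per-million with the track's library size, with optional control
subtraction (each track on its own RPM scale) floored at zero. This is the
ROSE-family ranking signal; the floor prevents negative ranks in
input-dominated regions. RPKM is the standard
`count / (length_kb × library_millions)`; per-condition eRNA RPKM is the
mean over replicate RPKMs (replicate combination is not otherwise
constrained; the mean keeps the estimator linear in counts). Fragment
counting uses ≥ 1 bp overlap, not midpoint, matching coverage-style
quantification. Counting is unstranded by default.

## Super-enhancer calling

Quality-filtered H3K27ac peaks are stitched at 12.5 kb with no
TSS-exclusion (the classic ROSE defaults; both exposed in configuration),
scored with the region signal above, and ranked descending with ties
broken toward the lower genomic coordinate. The cutoff operates on the
doubly-scaled ranked curve (x = rank fraction, y = signal / max): it is
the y value at the first index whose discrete slope exceeds 1 and remains
above 1 through a 3-point lookahead. The lookahead suppresses single-step
noise crossings, which raw discrete slopes produce freely near the elbow.
Two numerical details:

* the slope comparison uses a 1e−9 relative tie tolerance, so a curve that
  is exactly linear (all slopes 1 up to floating-point noise) yields no
  super-enhancers, as the strict inequality intends;
* all-equal signals yield cutoff 1 (no SEs) with a warning.

Classification is strictly above the cutoff and is scale-invariant:
multiplying all signals by a positive constant leaves the partition
unchanged. On the analytic curve y = x², the discrete cutoff reproduces
the continuous unit-slope tangent (y = 0.25 at x = 0.5) to within one
grid step.

SE targets: genes are "expressed" with FPKM strictly above 1 in every
replicate of at least one condition (conditions compiled by union), and
only protein-coding genes are candidates. Per SE, all overlapping
expressed genes (distance 0) and the nearest expressed gene on each flank
are reported, with edge-to-edge distances capped at ±200 kb measured from
the SE boundaries.

## Co-occupancy

A region is "bound" when ≥ 1 bp of a factor peak overlaps it (minimum
overlap configurable). Multi-mark classification assigns each peak to the
exact subset of marks it overlaps, so the 2^k class fractions are disjoint
and sum to 1; marks supplied as broad domains are handled identically to
point peaks. Peak-set comparison reports common entries in the first
set's coordinates (bedtools `-u` semantics) and condition-specific entries
with no cross-overlap.

## eRNA procedure

1. H3K27ac peaks with an H3K4me1 peak within a ±200 bp window are
   candidate enhancer anchors.
2. Anchors overlapping any exon padded by ±2 kb are discarded. The filter
   is applied to the H3K27ac anchor (the A side of the window join); the
   alternative — re-testing the locus window or the H3K4me1 partner — is
   defensible but the anchor-side filter matches an intersect `-v` applied
   to the joined peaks, keeps the filter independent of the locus width,
   and is the convention adopted here.
3. Each surviving anchor defines one locus: midpoint ± 600 bp, clipped
   (never dropped) at the chromosome start; clipped length is used in
   RPKM. Coordinate-identical loci are deduplicated.
4. Loci are expressed when RPKM is strictly above 0.3 in at least one
   condition (which condition is not constrained; "either" is the chosen
   and configurable reading).
5. Fold change is the signed ratio knockdown/control: r when r ≥ 1, −1/r
   otherwise, so the ±2 cutoff applies symmetrically; a zero on exactly
   one side maps to ±inf, and a double zero gives a null fold change. The
   numerator convention (knockdown over control) is declared, not
   inferred. Differential = expressed and strictly beyond ±2.
6. Loci are classed super/typical/none by ≥ 1 bp overlap with the SE/TE
   partition; overlapping SE/TE inputs are rejected because they cannot
   have come from one classification run.

## Synthetic landscape generator

The generator emulates the *statistical structure* the analysis assumes,
not sequencing reads. The genome (default 4 × 25 Mb) is carved into
100 kb tiles with 25 kb margins; genes, SE clusters and TE peaks each own
one tile, so planted features can never collide, and nothing can stitch
across plantings (margins exceed the stitch distance). Defaults define
the standard fixture: 200 genes (~10% non-coding biotypes, 2–8 exons
each), 20 SE clusters of 3–6 H3K27ac peaks (gaps 2–6 kb), 400 isolated TE
peaks. Peak heights are log-normal with log-means 6.0 (SE) vs 3.0 (TE)
and σ = 0.25 — about a 20× median separation, so the ranked curve has an
unambiguous elbow. Coverage tracks rebuild every peak as a flat-top
kernel on a uniform 0.05 background (library size 2 × 10⁷); with the
matching uniform control track subtracted, region signal equals planted
height × width exactly, so signal ordering is inherited from the
planting.

Occupancy fractions are planted deterministically (exactly
`round(f × n)` regions bound) rather than by Bernoulli draws, so recovery
tests are exact: factor peaks on 45% of SEs and 10% of TEs, repressive
domains (factor peak ± 2 kb) over 25% of factor peaks, H3K4me1 partners
within 0–199 bp of 70% of H3K27ac peaks (a gap equal to the 200 bp window
would not pair under half-open padding). Expression: 60% of
protein-coding genes at FPKM 2–50, the rest below 1.

eRNA counts are gamma-Poisson (negative-binomial-like) around
`mean = RPKM × length_kb × library_millions`, with base RPKM 4 (≈ 96
reads per replicate at the defaults) and dispersion 0.005. These defaults
put a null locus's fold-change noise (ratio sd ≈ 0.06) more than 5σ from
the ±2 cutoff, so planted |FC| ≥ 3 loci are always recovered and null
loci are never called — the regime the recovery checks define. 10% of
loci are planted at zero expression; 6 loci receive the planted signed
fold changes (±3, ±4, ±5 by default).

Everything is a pure function of the configuration (which contains the
seed); independent random streams are derived per stage, and regeneration
is bit-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (mappability, GC,
duplication), overlapping or nested genes, enhancers inside introns,
copy-number distortion of ChIP signal, biological replicate variability
beyond count noise, and continuous (rather than bimodal) enhancer-signal
distributions. On real data the SE/TE boundary is soft and the cutoff's
single-index placement carries real uncertainty; the synthetic elbow is
deliberately sharp so that correctness of the *procedure* is testable.

## Pipeline

Stages communicate via files in standard formats (BED, narrowPeak,
bedGraph, GTF, TSV), so any stage can be re-run or replaced by an
external tool for cross-validation. The run summary serializes every
threshold, count and fraction with sorted keys and no timestamps;
identical inputs and configuration reproduce it byte-for-byte. A stage
failure aborts with the stage named, retains completed outputs, and drops
a `FAILED` marker.

## Problem sizes

The test suite and acceptance script run the standard fixture
(420 stitched regions, ~350 eRNA loci, 200 genes) and reduced variants
(68 regions) across up to 20 seeds; oracle-equivalence checks use 50
random instances of up to 200 intervals. These sizes exercise every code
path while keeping the full suite in the seconds range.

## Known limitations

* The tangent cutoff is a single-index rule; when the two lowest SE
  signals in a landscape differ by less than one scaled grid step, the
  3-point lookahead can push the cutoff one region upward (visible as
  Jaccard 20/21 on a minority of seeds).
* Strand information is carried but not used in overlap logic; stranded
  eRNA quantification is out of scope.
* No statistical test accompanies the eRNA fold-change cutoff — by
  design, it is a plain threshold rule.
* `other`-category annotation collapses all non-coding biotypes; sub-RNA
  classes are not distinguished.
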