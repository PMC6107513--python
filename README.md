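# sekit

Super-enhancer calling, enhancer co-occupancy analysis, and enhancer-RNA
(eRNA) differential calling from ChIP-seq peaks, coverage tracks, and
RNA-seq counts — with a seeded synthetic-landscape generator for testing
and benchmarking.

## Who this is for

Regulatory-genomics analysts who have MACS-style peak calls (narrowPeak),
coverage (bedGraph), gene models (GTF), and expression tables, and who want
a reproducible, scriptable implementation of the classic enhancer-centric
analyses:

* **Super-enhancer (SE) identification** — ROSE-style: H3K27ac peaks are
  stitched when their genomic gap is ≤ 12.5 kb, each stitched region is
  scored by its reads-per-million-scaled (optionally input-subtracted)
  signal area, regions are ranked, and the hockey-stick cutoff separates
  SEs from typical enhancers (TEs). With signals sorted ascending and both
  axes scaled to [0, 1] (x_i = i/(n−1), y_i = s_i/max s), the cutoff is the
  y value where the discrete slope first exceeds 1 and stays above 1
  through a 3-point lookahead — the point where a unit-slope line is
  tangent to the ranked curve. Regions strictly above the cutoff are SEs.
* **SE target genes** — expressed protein-coding genes (FPKM > 1 in both
  replicates of at least one condition) overlapping or nearest to each SE
  on either side, within ±200 kb of the SE boundaries.
* **Peak annotation** — promoter (TSS to 2.5 kb upstream, strand-aware),
  intragenic, intergenic, or "other" (non-coding gene context), assigned by
  peak midpoint.
* **Co-occupancy** — fraction of regions bound by a factor (≥ 1 bp overlap,
  bedtools-intersect semantics), multi-mark overlap classes, common vs
  condition-specific peak-set comparison, and gene-set Venn counts.
* **eRNA analysis** — H3K27ac peaks with an H3K4me1 peak within ±200 bp,
  minus anchors within 2 kb of any exon, define ±600 bp loci at the anchor
  midpoint; loci are quantified as RPKM (mean over replicates), expressed
  if RPKM > 0.3 in at least one condition, and differential if the signed
  knockdown/control fold change is strictly beyond ±2.

The exact interval algebra underneath (window join, stitch/merge,
exclusion, closest-feature search, all 0-based half-open) is exposed in
`sekit.intervals` and is verified against brute-force oracles.

## Worked example

```python
from sekit.simulate import LandscapeConfig, generate
from sekit.superenhancer import build_stitched_enhancers, classify
from sekit.cooccupancy import fraction_regions_bound
from sekit.intervals import IntervalSet

ls = generate(LandscapeConfig(seed=1))   # 20 planted SEs vs 400 TEs
regions = build_stitched_enhancers(ls.h3k27ac_intervals, ls.track, ls.control_track)
supers, typicals = classify(regions)
print(len(supers), len(typicals))
bound = fraction_regions_bound(IntervalSet([r.region for r in supers]), ls.factor)
print(f"{bound.n_bound}/{bound.n_regions} SEs factor-bound "
      f"({100 * bound.fraction:.0f}%)")
```

prints

```
20 400
9/20 SEs factor-bound (45%)
```

— the 20 called super-enhancers are exactly the 20 planted high-signal
clusters, the 400 typical enhancers are the isolated low-signal peaks, and
the factor was planted on exactly 45% of SEs, which the co-occupancy
measurement recovers.

The same analysis from the shell:

```bash
sekit simulate --seed 1 --outdir fixture/
sekit run-all --config fixture/run_config.yaml
```

writes per-stage outputs (filtered peaks, annotation table, ranked
enhancer curve, SE/TE BEDs, SE target table, co-occupancy JSON, eRNA locus
table, differential-eRNA BED) plus a `summary.json` with every count,
fraction, and threshold of the run.

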