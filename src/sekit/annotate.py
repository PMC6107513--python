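"""Peak-to-gene annotation.

Each peak is placed, by its midpoint, into one of four genomic categories:

* ``promoter_tss`` — within the strand-aware promoter window, i.e. from the
  TSS to 2.5 kb upstream of a protein-coding gene;
* ``intragenic`` — inside a protein-coding gene body (introns, exons, UTRs
  collapsed);
* ``other`` — inside the body or promoter window of a pseudogene, miRNA or
  other small-RNA gene;
* ``intergenic`` — everything else.

Precedence is promoter_tss > intragenic > other > intergenic. Midpoint-based
assignment keeps the classification deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval, IntervalSet
from .io import GeneModel

CATEGORIES = ("promoter_tss", "intragenic", "intergenic", "other")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: GenomicInterval
    category: str
    assigned_gene: Optional[str] = None
    distance_to_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "promoter_tss":
            assert self.assigned_gene is not None
            assert self.distance_to_tss is not None and abs(self.distance_to_tss) <= 2500


def _tss_distance(mid: int, gene: GeneModel) -> int:
    """Signed strand-aware distance: negative upstream of the TSS."""
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def _in_promoter(mid: int, gene: GeneModel, upstream_bp: int) -> bool:
    d = _tss_distance(mid, gene)
    return -upstream_bp <= d <= 0


def _in_body(mid: int, gene: GeneModel) -> bool:
    return gene.body.start <= mid < gene.body.end


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_upstream_bp: int = 2500,
) -> AnnotatedPeak:
    """Categorise one peak against a gene set (see module docstring).

    Where the midpoint satisfies a rule for several genes, the gene with the
    nearest TSS wins; remaining ties go to the lower-coordinate gene.
    """
    mid = peak.midpoint
    on_chrom = [g for g in genes if g.chrom == peak.chrom]

    def nearest(cands: list[GeneModel]) -> GeneModel:
        return min(cands, key=lambda g: (abs(_tss_distance(mid, g)), g.body.start, g.gene_id))

    coding = [g for g in on_chrom if g.biotype == "protein_coding"]
    prom = [g for g in coding if _in_promoter(mid, g, promoter_upstream_bp)]
    if prom:
        g = nearest(prom)
        return AnnotatedPeak(peak, "promoter_tss", g.gene_id, _tss_distance(mid, g))
    body = [g for g in coding if _in_body(mid, g)]
    if body:
        g = nearest(body)
        return AnnotatedPeak(peak, "intragenic", g.gene_id, _tss_distance(mid, g))
    noncoding = [
        g
        for g in on_chrom
        if g.biotype != "protein_coding"
        and (_in_body(mid, g) or _in_promoter(mid, g, promoter_upstream_bp))
    ]
    if noncoding:
        g = nearest(noncoding)
        return AnnotatedPeak(peak, "other", g.gene_id, _tss_distance(mid, g))
    return AnnotatedPeak(peak, "intergenic", None, None)


def annotate_peaks(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_upstream_bp: int = 2500,
) -> list[AnnotatedPeak]:
    return [annotate_peak(p, genes, promoter_upstream_bp) for p in peaks]


def target_genes(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_upstream_bp: int = 2500,
) -> set[str]:
    """Genes receiving at least one promoter or gene-body peak.

    Intergenic peaks are not counted as targeting; peaks annotated ``other``
    point at non-coding genes and are likewise excluded.
    """
    return {
        a.assigned_gene
        for a in annotate_peaks(peaks, genes, promoter_upstream_bp)
        if a.category in ("promoter_tss", "intragenic") and a.assigned_gene
    }


def distribution_summary(annotated: Iterable[AnnotatedPeak]) -> dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    annotated = list(annotated)
    if not annotated:
        raise ValueError("cannot summarise an empty annotation set")
    n = len(annotated)
    return {cat: sum(a.category == cat for a in annotated) / n for cat in CATEGORIES}
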