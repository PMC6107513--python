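"""Super-enhancer calling from H3K27ac peaks.

The ROSE-style procedure: quality-filtered H3K27ac peaks are stitched into
enhancer regions (default gap 12.5 kb), each region is scored by its
RPM-scaled, optionally input-subtracted signal area, regions are ranked,
and the classic hockey-stick cutoff separates super-enhancers (SEs) from
typical enhancers (TEs): on the scaled rank/scaled signal curve, the cutoff
is the signal level where the discrete slope first exceeds 1 — the point
where a unit-slope line is tangent to the ranked curve.

SE target genes are the expressed protein-coding genes overlapping or
nearest to each SE on either side, within ±200 kb of the SE boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    IntervalSet,
    closest_features,
    stitch,
)
from .io import ExpressionTable, GeneModel
from .signal import CoverageTrack, region_signal

DEFAULT_STITCH_BP = 12_500
DEFAULT_MAX_TARGET_DIST_BP = 200_000


@dataclass
class StitchedRegion:
    """A stitched enhancer with its constituents, signal and rank."""

    region: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    signal: float
    rank: int = 0  # 1 = highest signal
    scaled_rank: float = 0.0
    scaled_signal: float = 0.0
    is_super: bool = False

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass(frozen=True)
class SeTargetAssignment:
    se: StitchedRegion
    genes: tuple[tuple[str, int], ...]  # (gene_id, signed edge-to-edge distance)


def build_stitched_enhancers(
    h3k27ac: IntervalSet,
    track: CoverageTrack,
    control: Optional[CoverageTrack] = None,
    stitch_distance_bp: int = DEFAULT_STITCH_BP,
) -> list[StitchedRegion]:
    """Stitch peaks, score each region, and rank descending by signal.

    Rank ties are broken toward the lower genomic coordinate so the output
    is deterministic. Input peaks should already be quality-filtered.
    """
    regions = [
        StitchedRegion(
            region=s.region,
            constituents=s.constituents,
            signal=region_signal(track, s.region, control),
        )
        for s in stitch(h3k27ac, stitch_distance_bp)
    ]
    regions.sort(key=lambda r: (-r.signal, r.region.chrom, r.region.start))
    for i, r in enumerate(regions, 1):
        r.rank = i
    return regions


def se_cutoff(signals: Sequence[float]) -> float:
    """Hockey-stick cutoff on the scaled-signal axis.

    Signals are sorted ascending and both axes scaled to [0, 1]
    (``x_i = i/(n-1)``, ``y_i = s_i / max(s)``). The cutoff is ``y`` at the
    first index whose discrete slope exceeds 1 and stays above 1 through a
    3-point lookahead (the lookahead suppresses single-step noise
    crossings). Regions strictly above the cutoff are super-enhancers.

    Degenerate inputs (all signals equal, or no slope ever exceeding 1)
    give cutoff 1.0, i.e. no super-enhancers.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 3:
        raise ValueError("need at least 3 signals to place a cutoff")
    if np.any(s < 0):
        raise ValueError("signals must be >= 0")
    smax = s[-1]
    if smax == 0 or s[0] == smax:
        warnings.warn("all signals equal; cutoff set to 1 (no super-enhancers)", stacklevel=2)
        return 1.0
    y = s / smax
    slopes = np.diff(y) * (n - 1)  # dx = 1/(n-1)
    # strict > with a relative tie tolerance: a slope equal to 1 at machine
    # precision (exactly linear curve) must not count as exceeding
    above = slopes > 1 + 1e-9
    for i in range(slopes.size):
        if above[i] and np.all(above[i : min(i + 3, slopes.size)]):
            return float(y[i])
    return 1.0


def classify(
    regions: Sequence[StitchedRegion],
) -> tuple[list[StitchedRegion], list[StitchedRegion]]:
    """Partition stitched regions into (super_enhancers, typical_enhancers).

    Fills in ``scaled_rank``, ``scaled_signal`` and ``is_super`` in place.
    The cutoff is scale-invariant: multiplying all signals by a positive
    constant leaves the partition unchanged.
    """
    regions = list(regions)
    if not regions:
        return [], []
    n = len(regions)
    smax = max(r.signal for r in regions)
    cutoff = se_cutoff([r.signal for r in regions]) if n >= 3 else 1.0
    for r in regions:
        r.scaled_rank = (r.rank - 1) / (n - 1) if n > 1 else 0.0
        r.scaled_signal = r.signal / smax if smax > 0 else 0.0
        r.is_super = r.scaled_signal > cutoff
    supers = [r for r in regions if r.is_super]
    typicals = [r for r in regions if not r.is_super]
    return supers, typicals


def expressed_genes(
    expr: ExpressionTable,
    genes: Optional[Sequence[GeneModel]] = None,
    fpkm_min: float = 1.0,
) -> set[str]:
    """Genes with FPKM strictly above ``fpkm_min`` in every replicate of at
    least one condition, compiled across conditions.

    If gene models are supplied the set is restricted to protein-coding
    genes (only those are considered as potential SE targets).
    """
    out = set()
    for gid, per_cond in expr.values.items():
        for cond in expr.conditions:
            reps = per_cond.get(cond, [])
            if len(reps) >= 2 and all(v > fpkm_min for v in reps):
                out.add(gid)
                break
    if genes is not None:
        coding = {g.gene_id for g in genes if g.biotype == "protein_coding"}
        out &= coding
    return out


def assign_se_targets(
    ses: Sequence[StitchedRegion],
    genes: Sequence[GeneModel],
    expressed: set[str],
    max_dist_bp: int = DEFAULT_MAX_TARGET_DIST_BP,
) -> list[SeTargetAssignment]:
    """Closest expressed genes flanking each SE, within ±``max_dist_bp``.

    Per SE: every overlapping expressed gene (distance 0) plus the nearest
    expressed gene on each side, distances measured between the SE edge and
    the gene-body edge. Genes beyond the distance cap are dropped.
    """
    unknown = expressed - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"expressed ids absent from gene models: {sorted(unknown)[:5]}")
    bodies = IntervalSet(
        [
            GenomicInterval(g.chrom, g.body.start, g.body.end, g.strand, g.gene_id)
            for g in genes
            if g.gene_id in expressed
        ],
        label="expressed_genes",
    )
    se_set = IntervalSet([s.region for s in ses])
    order = sorted(range(len(ses)), key=lambda i: (ses[i].region.chrom, ses[i].region.start, ses[i].region.end))
    results_sorted = closest_features(se_set, bodies)
    assignments: list[Optional[SeTargetAssignment]] = [None] * len(ses)
    for pos, res in zip(order, results_sorted):
        hits: list[tuple[str, int]] = [(h.feature.name, 0) for h in res.overlapping]
        for side in (res.upstream, res.downstream):
            if side is not None and abs(side.distance) <= max_dist_bp:
                hits.append((side.feature.name, side.distance))
        assignments[pos] = SeTargetAssignment(se=ses[pos], genes=tuple(hits))
    return [a for a in assignments if a is not None]
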