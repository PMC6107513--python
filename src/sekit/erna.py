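"""Enhancer-RNA (eRNA) identification, quantification and differential calling.

The procedure:

1. H3K27ac peaks with an H3K4me1 peak within ±200 bp are candidate
   enhancers (window join).
2. Candidates whose H3K27ac anchor overlaps any exon padded by ±2 kb are
   discarded (removes transcribed gene context).
3. Each surviving anchor defines an eRNA locus: a ±600 bp window around the
   anchor midpoint (clipped only at the chromosome start).
4. Loci are quantified as RPKM from total RNA-seq counts, averaged over
   replicates per condition; a locus is expressed if RPKM > 0.3 in at least
   one condition.
5. Differential loci are expressed loci with a signed fold change beyond
   ±2 between knockdown and control.
6. Loci are classed as super/typical/none by overlap with SE/TE regions.

The signed fold-change convention: ``r = RPKM_kd / RPKM_ctrl``; reported as
``r`` when ``r >= 1`` and ``-1/r`` otherwise, so the symmetric ">2 or <−2"
cutoff applies on both sides. A zero on exactly one side maps to ±inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, exclude_overlapping, window_join
from .signal import rpkm

DEFAULT_PAIR_WINDOW_BP = 200
DEFAULT_EXON_PAD_BP = 2_000
DEFAULT_HALF_WIDTH_BP = 600
DEFAULT_RPKM_MIN = 0.3
DEFAULT_FC_MIN = 2.0


@dataclass
class ErnaLocus:
    """A candidate eRNA locus anchored on an H3K27ac peak."""

    anchor_peak: GenomicInterval
    center: int
    locus: GenomicInterval
    rpkm: dict[str, float] = field(default_factory=dict)  # condition -> mean RPKM
    expressed: bool = False
    fold_change: Optional[float] = None
    is_differential: bool = False
    enhancer_class: str = "none"  # super | typical | none

    @property
    def key(self) -> str:
        return str(self.locus)


def identify_erna_loci(
    h3k27ac: IntervalSet,
    h3k4me1: IntervalSet,
    exons: Sequence[GenomicInterval],
    pair_window_bp: int = DEFAULT_PAIR_WINDOW_BP,
    exon_pad_bp: int = DEFAULT_EXON_PAD_BP,
    half_width_bp: int = DEFAULT_HALF_WIDTH_BP,
) -> list[ErnaLocus]:
    """Steps 1–3 of the procedure; returns deduplicated, sorted loci.

    The exon filter is applied to the H3K27ac anchor (the A side of the
    window join); the locus window itself is not re-tested. Loci identical
    in coordinates (two anchors sharing a midpoint) are deduplicated.
    """
    anchors = []
    seen_anchor = set()
    for a, _ in window_join(h3k27ac, h3k4me1, pair_window_bp):
        akey = (a.chrom, a.start, a.end)
        if akey not in seen_anchor:
            seen_anchor.add(akey)
            anchors.append(a)
    kept = exclude_overlapping(IntervalSet(anchors), IntervalSet(exons), exon_pad_bp)
    loci: list[ErnaLocus] = []
    seen_locus = set()
    for a in kept:
        center = a.midpoint
        start = max(0, center - half_width_bp)
        locus = GenomicInterval(a.chrom, start, center + half_width_bp, name=a.name)
        lkey = (locus.chrom, locus.start, locus.end)
        if lkey not in seen_locus:
            seen_locus.add(lkey)
            loci.append(ErnaLocus(anchor_peak=a, center=center, locus=locus))
    loci.sort(key=lambda l: (l.locus.chrom, l.locus.start, l.locus.end))
    return loci


def quantify(
    loci: Sequence[ErnaLocus],
    counts: pd.DataFrame,
    library_sizes: Mapping[str, Sequence[int]],
) -> list[ErnaLocus]:
    """Attach per-condition mean replicate RPKM to each locus.

    ``counts`` is indexed by locus key (``chrom:start-end``) with one column
    per replicate named ``<condition>_rep<k>``; ``library_sizes`` gives the
    matching per-replicate totals. Per-condition RPKM is the mean of the
    replicate RPKMs.
    """
    for cond, libs in library_sizes.items():
        cols = [f"{cond}_rep{k}" for k in range(1, len(libs) + 1)]
        missing = [c for c in cols if c not in counts.columns]
        if missing:
            raise ValueError(f"condition {cond!r}: missing replicate columns {missing}")
    for locus in loci:
        if locus.key not in counts.index:
            raise ValueError(f"no counts for locus {locus.key}")
        row = counts.loc[locus.key]
        locus.rpkm = {
            cond: sum(
                rpkm(int(row[f"{cond}_rep{k}"]), len(locus.locus), lib)
                for k, lib in enumerate(libs, 1)
            )
            / len(libs)
            for cond, libs in library_sizes.items()
        }
    return list(loci)


def signed_fold_change(ctrl: float, kd: float) -> Optional[float]:
    """Signed ratio kd/ctrl: r if r >= 1 else -1/r; ±inf if one side is 0."""
    if ctrl == 0 and kd == 0:
        return None
    if ctrl == 0:
        return math.inf
    if kd == 0:
        return -math.inf
    r = kd / ctrl
    return r if r >= 1 else -1.0 / r


def call_differential(
    loci: Sequence[ErnaLocus],
    control: str,
    knockdown: str,
    rpkm_min: float = DEFAULT_RPKM_MIN,
    fc_min: float = DEFAULT_FC_MIN,
) -> list[ErnaLocus]:
    """Flag expressed and differential loci (strict thresholds).

    Expressed: RPKM strictly above ``rpkm_min`` in at least one condition.
    Differential: expressed and signed fold change strictly beyond
    ±``fc_min``.
    """
    for locus in loci:
        missing = {control, knockdown} - set(locus.rpkm)
        if missing:
            raise ValueError(f"locus {locus.key} lacks RPKM for {sorted(missing)}")
        ctrl, kd = locus.rpkm[control], locus.rpkm[knockdown]
        locus.expressed = ctrl > rpkm_min or kd > rpkm_min
        locus.fold_change = signed_fold_change(ctrl, kd)
        fc = locus.fold_change
        locus.is_differential = bool(
            locus.expressed and fc is not None and (fc > fc_min or fc < -fc_min)
        )
    return list(loci)


def classify_by_enhancer(
    loci: Sequence[ErnaLocus],
    ses: IntervalSet,
    typicals: IntervalSet,
) -> list[ErnaLocus]:
    """Label each locus super/typical/none by >= 1 bp overlap.

    SE and TE inputs must be disjoint (they come from one partition of the
    stitched regions); overlapping inputs are rejected.
    """
    for se in ses:
        if typicals.any_overlap(se):
            raise ValueError(f"SE {se} overlaps a typical enhancer; sets must be disjoint")
    for locus in loci:
        if ses.any_overlap(locus.locus):
            locus.enhancer_class = "super"
        elif typicals.any_overlap(locus.locus):
            locus.enhancer_class = "typical"
        else:
            locus.enhancer_class = "none"
    return list(loci)


def loci_to_frame(loci: Sequence[ErnaLocus]) -> pd.DataFrame:
    """Flatten loci to a tidy table (one row per locus)."""
    rows = []
    for l in loci:
        row = {
            "locus": l.key,
            "anchor": str(l.anchor_peak),
            "expressed": l.expressed,
            "fold_change": l.fold_change,
            "is_differential": l.is_differential,
            "enhancer_class": l.enhancer_class,
        }
        for cond, v in l.rpkm.items():
            row[f"rpkm_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
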