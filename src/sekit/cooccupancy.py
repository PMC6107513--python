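"""Factor–region co-occupancy and peak-set comparison.

"Bound"/"decorated"/"containing" are all operationalised as a >= 1 bp
overlap between a region and a factor peak (``bedtools intersect``
semantics); the minimum overlap is exposed for stricter definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .intervals import IntervalSet


@dataclass(frozen=True)
class CooccupancySummary:
    region_label: str
    factor_label: str
    n_regions: int
    n_bound: int

    @property
    def fraction(self) -> float:
        return self.n_bound / self.n_regions


@dataclass(frozen=True)
class PeakSetComparison:
    """Common vs condition-specific peaks between two peak sets.

    ``common`` is reported in set1's coordinates (``bedtools intersect -u``
    semantics); each input entry lands in exactly one of its two bins.
    """

    common: IntervalSet
    set1_specific: IntervalSet
    set2_specific: IntervalSet


def fraction_regions_bound(
    regions: IntervalSet,
    factor_peaks: IntervalSet,
    min_bp: int = 1,
) -> CooccupancySummary:
    """Fraction of regions overlapped by >= 1 factor peak (>= ``min_bp`` bp)."""
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    n_bound = sum(factor_peaks.any_overlap(r, min_bp) for r in regions)
    return CooccupancySummary(
        region_label=regions.label,
        factor_label=factor_peaks.label,
        n_regions=len(regions),
        n_bound=n_bound,
    )


def multi_mark_fraction(
    peaks: IntervalSet,
    mark_sets: Sequence[IntervalSet],
    min_bp: int = 1,
) -> dict[frozenset[str], float]:
    """Fractions of peaks in each of the 2^k mark-overlap classes.

    Keys are frozensets of mark labels (empty = overlapping no mark); the
    class of a peak is the exact set of marks it overlaps, so the fractions
    are disjoint and sum to 1.
    """
    if not mark_sets:
        raise ValueError("need at least one mark set")
    labels = [m.label or f"mark{i}" for i, m in enumerate(mark_sets, 1)]
    classes: dict[frozenset[str], int] = {
        frozenset(c): 0
        for k in range(len(labels) + 1)
        for c in combinations(labels, k)
    }
    for p in peaks:
        hit = frozenset(
            lab for lab, marks in zip(labels, mark_sets) if marks.any_overlap(p, min_bp)
        )
        classes[hit] += 1
    n = len(peaks)
    return {cls: count / n for cls, count in classes.items()} if n else {
        cls: 0.0 for cls in classes
    }


def compare_peak_sets(
    set1: IntervalSet, set2: IntervalSet, min_bp: int = 1
) -> PeakSetComparison:
    """Split two peak sets into common and condition-specific entries."""
    common, spec1 = [], []
    for p in set1:
        (common if set2.any_overlap(p, min_bp) else spec1).append(p)
    spec2 = [p for p in set2 if not set1.any_overlap(p, min_bp)]
    return PeakSetComparison(
        common=IntervalSet(common, label=f"{set1.label}_common"),
        set1_specific=IntervalSet(spec1, label=f"{set1.label}_specific"),
        set2_specific=IntervalSet(spec2, label=f"{set2.label}_specific"),
    )


def gene_set_overlap(sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Venn-class counts for 2–3 named gene-id sets.

    Keys are frozensets of set names; the value counts genes belonging to
    exactly those sets. Class counts reconcile with each input cardinality.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("gene_set_overlap supports 2 or 3 sets")
    names = list(sets)
    universe = set().union(*sets.values())
    classes: dict[frozenset[str], int] = {
        frozenset(c): 0 for k in range(1, len(names) + 1) for c in combinations(names, k)
    }
    for g in universe:
        cls = frozenset(n for n in names if g in sets[n])
        classes[cls] += 1
    return classes
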