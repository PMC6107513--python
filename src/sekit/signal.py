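"""Coverage aggregation and RPKM.

A :class:`CoverageTrack` is a stepwise per-base signal (bedGraph semantics)
plus a library size; region signal is the reads-per-million-scaled area
under the track, optionally background-subtracted against a control track
and floored at zero — the ranking signal used for stitched enhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet


@dataclass
class CoverageTrack:
    """Per-chromosome sorted, non-overlapping coverage steps.

    ``library_size`` is the total mapped reads used for RPM scaling;
    ``None`` means "already on the desired scale" (treated as 1e6, i.e. a
    scale factor of 1).
    """

    _steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    library_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, (starts, ends, values) in self._steps.items():
            if np.any(values < 0):
                raise ValueError(f"negative coverage values on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or unsorted steps on {chrom}")
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted step on {chrom}")

    @classmethod
    def from_steps(
        cls,
        steps: Mapping[str, Sequence[tuple[int, int, float]]],
        library_size: Optional[int] = None,
    ) -> "CoverageTrack":
        packed = {}
        for chrom, triples in steps.items():
            triples = sorted(triples)
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            packed[chrom] = (starts, ends, values)
        return cls(packed, library_size=library_size)

    @property
    def chroms(self) -> list[str]:
        return list(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._steps[chrom]

    @property
    def rpm_factor(self) -> float:
        return 1.0 if self.library_size is None else 1e6 / self.library_size

    def area(self, region: GenomicInterval) -> float:
        """Raw (unscaled) area under the track within ``region``."""
        if region.chrom not in self._steps:
            return 0.0
        starts, ends, values = self._steps[region.chrom]
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        return float(np.sum((e - s) * values[lo:hi]))


def region_signal(
    track: CoverageTrack,
    region: GenomicInterval,
    control: Optional[CoverageTrack] = None,
) -> float:
    """RPM-scaled signal area over ``region``, control-subtracted, floored at 0.

    Each track is scaled to reads-per-million with its own library size
    before subtraction, so treatment and control are depth-comparable.
    A region on a chromosome absent from the track scores 0 with a warning.
    """
    if region.chrom not in track._steps:
        warnings.warn(f"chromosome {region.chrom} absent from track; signal 0", stacklevel=2)
        return 0.0
    signal = track.area(region) * track.rpm_factor
    if control is not None:
        signal -= control.area(region) * control.rpm_factor
    return max(signal, 0.0)


def rpkm(count: int, region_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / ((region_length_bp / 1e3) * (library_size / 1e6))


def count_fragments(fragments: IntervalSet, region: GenomicInterval) -> int:
    """Number of fragments overlapping ``region`` by >= 1 bp."""
    return len(fragments.overlapping(region))
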