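"""Readers and writers for the formats the pipeline touches.

BED3/BED6, narrowPeak (BED6+4), bedGraph, GTF and TSV expression matrices.
All genomic coordinates are converted to 0-based half-open on read (GTF is
1-based inclusive on disk). Tabular parsing goes through pandas; GTF parsing
through :mod:`gffutils`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gffutils
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .signal import CoverageTrack

PathLike = Union[str, Path]

BIOTYPES = ("protein_coding", "pseudogene", "miRNA", "other_small")


class FormatError(ValueError):
    """A malformed line in an input file, reported with file and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One MACS-style narrowPeak record.

    ``signal_value`` holds the fold enrichment over background; p/q values
    are stored as -log10 (``-1`` is the missing-value sentinel);
    ``summit_offset`` is bp from the peak start, ``-1`` if absent.
    """

    interval: GenomicInterval
    signal_value: float
    neg_log10_p: float
    neg_log10_q: float
    summit_offset: int = -1

    def __post_init__(self) -> None:
        for v in (self.neg_log10_p, self.neg_log10_q):
            if v < 0 and v != -1:
                raise ValueError("-log10 p/q must be >= 0 or the sentinel -1")
        if self.summit_offset >= len(self.interval):
            raise ValueError("summit_offset must fall inside the peak")


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, strand, body, exons and a coarse biotype.

    The TSS is the strand-aware 5' end of the body: ``body.start`` on "+",
    ``body.end - 1`` on "-". Biotypes are collapsed to the four annotation
    classes the peak annotator distinguishes.
    """

    gene_id: str
    chrom: str
    strand: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"biotype must be one of {BIOTYPES}")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(f"exon {ex} outside gene body {self.body}")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass
class ExpressionTable:
    """Per-replicate FPKM values keyed by gene and condition."""

    values: dict[str, dict[str, list[float]]]
    conditions: list[str]

    def fpkm(self, gene_id: str, condition: str) -> list[float]:
        return self.values[gene_id][condition]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values)


# ---------------------------------------------------------------------------
# BED / narrowPeak / bedGraph


def _check_coords(path: PathLike, lineno: int, start: str, end: str) -> tuple[int, int]:
    try:
        s, e = int(start), int(end)
    except ValueError:
        raise FormatError(path, lineno, f"non-integer coordinates {start!r}, {end!r}")
    if s < 0 or s >= e:
        raise FormatError(path, lineno, f"need 0 <= start < end, got [{s}, {e})")
    return s, e


def read_bed(path: PathLike, label: str = "") -> IntervalSet:
    """Read BED3/BED6 into a sorted :class:`IntervalSet`.

    Missing name fields are auto-generated as ``<label>_<N>``; the score and
    strand columns are optional.
    """
    label = label or Path(path).stem
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(path, lineno, f"expected >= 3 BED columns, got {len(f)}")
            start, end = _check_coords(path, lineno, f[1], f[2])
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"{label}_{lineno}"
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            ivs.append(GenomicInterval(f[0], start, end, strand, name, score))
    return IntervalSet(ivs, label=label)


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write BED6 (name/score/strand filled with defaults where absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:g}\t{iv.strand}\n"
            )


def read_narrowpeak(path: PathLike, label: str = "") -> list[NarrowPeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file."""
    label = label or Path(path).stem
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(path, lineno, f"expected 10 narrowPeak columns, got {len(f)}")
            start, end = _check_coords(path, lineno, f[1], f[2])
            name = f[3] if f[3] not in (".", "") else f"{label}_{lineno}"
            iv = GenomicInterval(f[0], start, end, f[5] if f[5] in "+-" else ".", name)
            records.append(
                NarrowPeakRecord(
                    interval=iv,
                    signal_value=float(f[6]),
                    neg_log10_p=float(f[7]),
                    neg_log10_q=float(f[8]),
                    summit_offset=int(f[9]),
                )
            )
    return records


def write_narrowpeak(records: Iterable[NarrowPeakRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\t"
                f"{r.signal_value:g}\t{r.neg_log10_p:g}\t{r.neg_log10_q:g}\t{r.summit_offset}\n"
            )


def read_bedgraph(path: PathLike, library_size: Optional[int] = None) -> CoverageTrack:
    """Read a bedGraph into a :class:`CoverageTrack`.

    bedGraph carries no library size; pass it explicitly to enable
    reads-per-million scaling (``None`` leaves signal on the raw scale,
    equivalent to a library of 1e6).
    """
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(path, lineno, f"expected 4 bedGraph columns, got {len(f)}")
            start, end = _check_coords(path, lineno, f[1], f[2])
            value = float(f[3])
            if value < 0:
                raise FormatError(path, lineno, f"negative coverage {value}")
            steps.setdefault(f[0], []).append((start, end, value))
    return CoverageTrack.from_steps(steps, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path: PathLike, omit_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.steps(chrom)
            for s, e, v in zip(starts, ends, values):
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GTF


_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "miRNA": "miRNA",
    "snoRNA": "other_small",
    "snRNA": "other_small",
}


def _collapse_biotype(raw: str) -> str:
    if raw in _BIOTYPE_MAP:
        return _BIOTYPE_MAP[raw]
    if "pseudogene" in raw:
        return "pseudogene"
    return "other_small"


def read_gtf(path: PathLike) -> list[GeneModel]:
    """Read gene and exon features from a GTF into :class:`GeneModel` objects.

    GTF coordinates (1-based, end-inclusive) are converted to 0-based
    half-open. The ``gene_type``/``gene_biotype`` attribute is collapsed to
    the four-way biotype used by the peak annotator.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        exons_by_gene.setdefault(gid, []).append(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
        )
    genes = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        raw_bt = (
            g.attributes.get("gene_type", g.attributes.get("gene_biotype", ["protein_coding"]))
        )[0]
        body = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand, name=gid)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=g.seqid,
                strand=g.strand,
                body=body,
                exons=tuple(sorted(exons_by_gene.get(gid, []), key=lambda e: e.start)),
                biotype=_collapse_biotype(raw_bt),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.body.start, g.body.end))
    return genes


def write_gtf(genes: Sequence[GeneModel], path: PathLike, source: str = "sekit") -> None:
    """Write gene + exon features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{_gtf_biotype(g.biotype)}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def _gtf_biotype(biotype: str) -> str:
    return {"other_small": "snoRNA"}.get(biotype, biotype)


# ---------------------------------------------------------------------------
# Expression table


def read_expression(path: PathLike) -> ExpressionTable:
    """Read a TSV FPKM matrix with columns ``gene_id, <condition>_rep<k>...``."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(path, 1, "expression table must have a gene_id column")
    cond_reps: list[tuple[str, str]] = []
    for col in df.columns:
        if col == "gene_id":
            continue
        cond, _, rep = col.rpartition("_rep")
        if not cond or not rep.isdigit():
            raise FormatError(path, 1, f"column {col!r} does not match <condition>_rep<k>")
        cond_reps.append((cond, col))
    conditions = sorted({c for c, _ in cond_reps})
    if (df[[col for _, col in cond_reps]] < 0).any().any():
        raise FormatError(path, 1, "FPKM values must be >= 0")
    values: dict[str, dict[str, list[float]]] = {}
    for _, row in df.iterrows():
        gid = str(row["gene_id"])
        values[gid] = {
            cond: [float(row[col]) for c, col in cond_reps if c == cond]
            for cond in conditions
        }
    return ExpressionTable(values=values, conditions=conditions)


def write_expression(table: ExpressionTable, path: PathLike) -> None:
    cols = ["gene_id"]
    first = next(iter(table.values.values()), {})
    for cond in table.conditions:
        for k in range(1, len(first.get(cond, [])) + 1):
            cols.append(f"{cond}_rep{k}")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gid, per_cond in table.values.items():
            row = [gid] + [
                f"{v:g}" for cond in table.conditions for v in per_cond[cond]
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Peak-quality filter


def filter_peaks(
    peaks: Sequence[NarrowPeakRecord],
    min_fold: float = 4.0,
    max_q: float = 0.05,
) -> IntervalSet:
    """Keep peaks with fold enrichment strictly above ``min_fold`` and
    q-value strictly below ``max_q``.

    Thresholding is done in -log10 space (``neg_log10_q > -log10(max_q)``)
    to avoid underflow on extreme q-values. Records carrying the ``-1``
    q-value sentinel are dropped and counted in a warning.
    """
    q_thresh = -math.log10(max_q)
    kept, n_sentinel = [], 0
    for r in peaks:
        if r.neg_log10_q == -1:
            n_sentinel += 1
            continue
        if r.signal_value > min_fold and r.neg_log10_q > q_thresh:
            kept.append(r.interval)
    if n_sentinel:
        warnings.warn(
            f"{n_sentinel} peak(s) excluded for missing q-value (sentinel -1)",
            stacklevel=2,
        )
    return IntervalSet(kept, label="filtered_peaks")
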