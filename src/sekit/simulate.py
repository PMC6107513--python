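"""Seeded synthetic enhancer-landscape generator with a ground-truth manifest.

The generator emulates the statistical structure the analysis assumes, not
read-level sequencing data:

* a toy genome of a few chromosomes carved into well-separated tiles, so
  planted features can never collide or stitch across plantings;
* gene models (2–8 exons each, ~10% non-coding biotypes);
* an enhancer landscape: clusters of high-signal H3K27ac peaks (planted
  super-enhancers) versus isolated typical-enhancer peaks, with log-normal
  peak heights separated in log-space so the ranked signal curve has a
  clear elbow;
* H3K4me1 partner peaks within ±200 bp of a configurable fraction of the
  H3K27ac peaks; a factor bound to exact fractions of SEs and TEs;
  repressive-mark domains over an exact fraction of factor peaks
  (deterministic planting, so recovery checks are exact);
* coverage tracks that rebuild every peak as a flat-top kernel over a
  uniform background, so region signal ordering matches planted signals;
* eRNA count tables for two conditions with planted signed fold changes.

Everything is a pure function of the configuration (which includes the
seed): regenerating with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .erna import ErnaLocus, identify_erna_loci
from .intervals import GenomicInterval, IntervalSet
from .io import (
    ExpressionTable,
    GeneModel,
    NarrowPeakRecord,
    write_bed,
    write_bedgraph,
    write_expression,
    write_gtf,
    write_narrowpeak,
)
from .signal import CoverageTrack

TILE_BP = 100_000
ZONE_MARGIN_BP = 25_000  # > stitch distance, so tiles never merge


@dataclass(frozen=True)
class LandscapeConfig:
    """All knobs of the generator; defaults define the standard fixture."""

    seed: int = 1
    n_chroms: int = 4
    chrom_length_bp: int = 25_000_000
    n_genes: int = 200
    n_se: int = 20
    n_te: int = 400
    se_constituents: tuple[int, int] = (3, 6)
    se_signal_mu: float = 6.0  # log-space per-peak coverage height
    te_signal_mu: float = 3.0
    signal_sigma: float = 0.25
    h3k4me1_frac: float = 0.7
    factor_frac_se: float = 0.45
    factor_frac_te: float = 0.10
    repressive_frac: float = 0.25
    expressed_frac: float = 0.6
    noncoding_frac: float = 0.10
    n_erna_de: int = 6
    planted_fc: tuple[float, ...] = (3.0, -3.0, 4.0, -4.0, 5.0, -5.0)
    erna_zero_frac: float = 0.10
    erna_base_rpkm: float = 4.0
    n_replicates: int = 2
    dispersion: float = 0.005
    library_size: int = 20_000_000
    background: float = 0.05
    condition_control: str = "shCTR"
    condition_knockdown: str = "shKD"

    def __post_init__(self) -> None:
        for name in ("h3k4me1_frac", "factor_frac_se", "factor_frac_te",
                     "repressive_frac", "expressed_frac", "erna_zero_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.se_signal_mu <= self.te_signal_mu:
            raise ValueError("se_signal_mu must exceed te_signal_mu (the elbow must exist)")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.condition_control, self.condition_knockdown)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandscapeConfig":
        d = dict(d)
        for key in ("se_constituents", "planted_fc"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruthManifest:
    """Planted truth, fully determined by the configuration."""

    config: LandscapeConfig
    se_regions: list[GenomicInterval]
    te_regions: list[GenomicInterval]
    se_factor_bound: list[bool]
    te_factor_bound: list[bool]
    factor_peaks: list[GenomicInterval]
    factor_repressive_overlap: list[bool]
    h3k27ac_partnered: list[bool]  # per H3K27ac peak, in sorted peak order
    expressed_genes: list[str]
    erna_truth: dict[str, dict]  # locus key -> {rpkm per condition, fc}

    def to_json(self, path) -> None:
        def iv(x: GenomicInterval):
            return [x.chrom, x.start, x.end]

        payload = {
            "config": self.config.to_dict(),
            "se_regions": [iv(r) for r in self.se_regions],
            "te_regions": [iv(r) for r in self.te_regions],
            "se_factor_bound": self.se_factor_bound,
            "te_factor_bound": self.te_factor_bound,
            "factor_peaks": [iv(r) for r in self.factor_peaks],
            "factor_repressive_overlap": self.factor_repressive_overlap,
            "h3k27ac_partnered": self.h3k27ac_partnered,
            "expressed_genes": self.expressed_genes,
            "erna_truth": self.erna_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)

        def iv(t):
            return GenomicInterval(t[0], t[1], t[2])

        return cls(
            config=LandscapeConfig.from_dict(d["config"]),
            se_regions=[iv(t) for t in d["se_regions"]],
            te_regions=[iv(t) for t in d["te_regions"]],
            se_factor_bound=d["se_factor_bound"],
            te_factor_bound=d["te_factor_bound"],
            factor_peaks=[iv(t) for t in d["factor_peaks"]],
            factor_repressive_overlap=d["factor_repressive_overlap"],
            h3k27ac_partnered=d["h3k27ac_partnered"],
            expressed_genes=d["expressed_genes"],
            erna_truth=d["erna_truth"],
        )


@dataclass
class Landscape:
    """The in-memory fixture: peak sets, tracks, genes, expression, truth."""

    config: LandscapeConfig
    genes: list[GeneModel]
    h3k27ac: list[NarrowPeakRecord]
    h3k4me1: IntervalSet
    factor: IntervalSet
    repressive: IntervalSet
    track: CoverageTrack
    control_track: CoverageTrack
    expression: ExpressionTable
    manifest: GroundTruthManifest

    @property
    def h3k27ac_intervals(self) -> IntervalSet:
        return IntervalSet([r.interval for r in self.h3k27ac], label="h3k27ac")


def _exact_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def _tiles(cfg: LandscapeConfig) -> list[tuple[str, int]]:
    per_chrom = cfg.chrom_length_bp // TILE_BP
    return [
        (f"chr{c + 1}", t * TILE_BP)
        for c in range(cfg.n_chroms)
        for t in range(per_chrom)
    ]


def make_genome(cfg: LandscapeConfig) -> list[GeneModel]:
    """Non-overlapping gene models placed on their own genome tiles."""
    rng = np.random.default_rng([cfg.seed, 0])
    tiles = _tiles(cfg)
    needed = cfg.n_genes + cfg.n_se + cfg.n_te
    if needed > len(tiles):
        raise ValueError(
            f"genome too small: need {needed} tiles of {TILE_BP} bp, have {len(tiles)}"
        )
    order = rng.permutation(len(tiles))
    genes = []
    for i in range(cfg.n_genes):
        chrom, tile_start = tiles[order[i]]
        zone_start = tile_start + ZONE_MARGIN_BP
        zone_len = TILE_BP - 2 * ZONE_MARGIN_BP
        body_len = int(rng.integers(5_000, 40_000))
        start = zone_start + int(rng.integers(0, zone_len - body_len))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        chunk = body_len // n_exons
        exons = []
        for k in range(n_exons):
            c0 = start + k * chunk
            ex_len = int(rng.integers(100, max(101, chunk // 3)))
            ex_start = c0 + int(rng.integers(0, max(1, chunk - ex_len)))
            exons.append(GenomicInterval(chrom, ex_start, ex_start + ex_len, strand))
        if rng.random() < cfg.noncoding_frac:
            biotype = "pseudogene" if rng.random() < 0.5 else "miRNA"
        else:
            biotype = "protein_coding"
        gid = f"gene{i + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                body=GenomicInterval(chrom, start, start + body_len, strand, name=gid),
                exons=tuple(exons),
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.body.start))
    return genes


def make_landscape(cfg: LandscapeConfig, genes: Sequence[GeneModel]) -> Landscape:
    """Plant the enhancer landscape on the tiles the genome left free."""
    rng = np.random.default_rng([cfg.seed, 1])
    # consume the same tile permutation as make_genome so plantings never collide
    tile_rng = np.random.default_rng([cfg.seed, 0])
    tiles = _tiles(cfg)
    order = tile_rng.permutation(len(tiles))
    enhancer_tiles = [tiles[order[cfg.n_genes + i]] for i in range(cfg.n_se + cfg.n_te)]

    zone_len = TILE_BP - 2 * ZONE_MARGIN_BP
    h3k27ac: list[NarrowPeakRecord] = []
    se_regions: list[GenomicInterval] = []
    te_regions: list[GenomicInterval] = []
    c_lo, c_hi = cfg.se_constituents

    def make_peak(chrom: str, start: int, width: int, height: float, name: str):
        iv = GenomicInterval(chrom, start, start + width, name=name)
        fold = height / cfg.background
        h3k27ac.append(
            NarrowPeakRecord(
                interval=iv,
                signal_value=fold,
                neg_log10_p=10.0,
                neg_log10_q=6.0,
                summit_offset=width // 2,
            )
        )
        return iv, height

    heights: dict[tuple[str, int, int], float] = {}
    for i in range(cfg.n_se):
        chrom, tile_start = enhancer_tiles[i]
        m = int(rng.integers(c_lo, c_hi + 1))
        widths = rng.integers(800, 1601, size=m)
        gaps = rng.integers(2_000, 6_001, size=m - 1) if m > 1 else np.array([], dtype=int)
        span = int(widths.sum() + gaps.sum())
        offset = tile_start + ZONE_MARGIN_BP + int(rng.integers(0, zone_len - span))
        pos = offset
        first, last = None, None
        for j in range(m):
            h = float(np.exp(rng.normal(cfg.se_signal_mu, cfg.signal_sigma)))
            iv, _ = make_peak(chrom, pos, int(widths[j]), h, f"h3k27ac_se{i}_{j}")
            heights[(iv.chrom, iv.start, iv.end)] = h
            first = first or iv
            last = iv
            pos = iv.end + (int(gaps[j]) if j < m - 1 else 0)
        se_regions.append(GenomicInterval(chrom, first.start, last.end, name=f"SE{i}"))
    for i in range(cfg.n_te):
        chrom, tile_start = enhancer_tiles[cfg.n_se + i]
        width = int(rng.integers(800, 1601))
        start = tile_start + ZONE_MARGIN_BP + int(rng.integers(0, zone_len - width))
        h = float(np.exp(rng.normal(cfg.te_signal_mu, cfg.signal_sigma)))
        iv, _ = make_peak(chrom, start, width, h, f"h3k27ac_te{i}")
        heights[(iv.chrom, iv.start, iv.end)] = h
        te_regions.append(iv)

    h3k27ac.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    se_regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    te_regions.sort(key=lambda r: (r.chrom, r.start, r.end))

    # H3K4me1 partners within +0..200 bp of an exact fraction of H3K27ac peaks
    n_peaks = len(h3k27ac)
    n_partnered = _exact_count(cfg.h3k4me1_frac, n_peaks)
    partner_idx = set(rng.choice(n_peaks, size=n_partnered, replace=False).tolist())
    partnered_flags = [i in partner_idx for i in range(n_peaks)]
    h3k4me1 = []
    for i in sorted(partner_idx):
        anchor = h3k27ac[i].interval
        # gap strictly below the ±200 bp pairing window (gap == window does
        # not pair under half-open padding)
        gap = int(rng.integers(0, 200))
        h3k4me1.append(
            GenomicInterval(
                anchor.chrom, anchor.end + gap, anchor.end + gap + 400,
                name=f"h3k4me1_{i}",
            )
        )

    # factor peaks on exact fractions of SEs and TEs (deterministic planting)
    n_se_bound = _exact_count(cfg.factor_frac_se, cfg.n_se)
    n_te_bound = _exact_count(cfg.factor_frac_te, cfg.n_te)
    se_bound_idx = set(rng.choice(cfg.n_se, size=n_se_bound, replace=False).tolist())
    te_bound_idx = set(rng.choice(cfg.n_te, size=n_te_bound, replace=False).tolist())
    factor = []
    for i in sorted(se_bound_idx):
        c = se_regions[i].midpoint
        factor.append(GenomicInterval(se_regions[i].chrom, c - 200, c + 200, name=f"factor_se{i}"))
    for i in sorted(te_bound_idx):
        c = te_regions[i].midpoint
        factor.append(GenomicInterval(te_regions[i].chrom, c - 200, c + 200, name=f"factor_te{i}"))
    factor.sort(key=lambda r: (r.chrom, r.start, r.end))

    # repressive domains over an exact fraction of factor peaks
    n_rep = _exact_count(cfg.repressive_frac, len(factor))
    rep_idx = set(rng.choice(len(factor), size=n_rep, replace=False).tolist()) if factor else set()
    rep_flags = [i in rep_idx for i in range(len(factor))]
    repressive = [factor[i].pad(2_000) for i in sorted(rep_idx)]

    # coverage: flat-top kernel per H3K27ac peak over a uniform background
    track = _build_track(cfg, h3k27ac, heights)
    control_track = _background_track(cfg)

    # expression: exact fraction of protein-coding genes expressed
    expression, expressed = _make_expression(cfg, genes, rng)

    manifest = GroundTruthManifest(
        config=cfg,
        se_regions=se_regions,
        te_regions=te_regions,
        se_factor_bound=[i in se_bound_idx for i in range(cfg.n_se)],
        te_factor_bound=[i in te_bound_idx for i in range(cfg.n_te)],
        factor_peaks=factor,
        factor_repressive_overlap=rep_flags,
        h3k27ac_partnered=partnered_flags,
        expressed_genes=sorted(expressed),
        erna_truth={},
    )
    return Landscape(
        config=cfg,
        genes=list(genes),
        h3k27ac=h3k27ac,
        h3k4me1=IntervalSet(h3k4me1, label="h3k4me1"),
        factor=IntervalSet(factor, label="factor"),
        repressive=IntervalSet(repressive, label="repressive"),
        track=track,
        control_track=control_track,
        expression=expression,
        manifest=manifest,
    )


def _build_track(
    cfg: LandscapeConfig,
    peaks: Sequence[NarrowPeakRecord],
    heights: dict[tuple[str, int, int], float],
) -> CoverageTrack:
    steps: dict[str, list[tuple[int, int, float]]] = {
        f"chr{c + 1}": [] for c in range(cfg.n_chroms)
    }
    by_chrom: dict[str, list[NarrowPeakRecord]] = {}
    for r in peaks:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for chrom, chrom_steps in steps.items():
        pos = 0
        for r in by_chrom.get(chrom, []):
            iv = r.interval
            if iv.start > pos:
                chrom_steps.append((pos, iv.start, cfg.background))
            h = heights[(iv.chrom, iv.start, iv.end)]
            chrom_steps.append((iv.start, iv.end, cfg.background + h))
            pos = iv.end
        if pos < cfg.chrom_length_bp:
            chrom_steps.append((pos, cfg.chrom_length_bp, cfg.background))
    return CoverageTrack.from_steps(steps, library_size=cfg.library_size)


def _background_track(cfg: LandscapeConfig) -> CoverageTrack:
    steps = {
        f"chr{c + 1}": [(0, cfg.chrom_length_bp, cfg.background)]
        for c in range(cfg.n_chroms)
    }
    return CoverageTrack.from_steps(steps, library_size=cfg.library_size)


def _make_expression(
    cfg: LandscapeConfig, genes: Sequence[GeneModel], rng: np.random.Generator
) -> tuple[ExpressionTable, set[str]]:
    coding = [g.gene_id for g in genes if g.biotype == "protein_coding"]
    n_expr = _exact_count(cfg.expressed_frac, len(coding))
    expr_idx = set(rng.choice(len(coding), size=n_expr, replace=False).tolist())
    expressed = {coding[i] for i in expr_idx}
    conditions = list(cfg.conditions)
    values: dict[str, dict[str, list[float]]] = {}
    for g in genes:
        per_cond = {}
        for cond in conditions:
            if g.gene_id in expressed:
                per_cond[cond] = [float(rng.uniform(2.0, 50.0)) for _ in range(cfg.n_replicates)]
            else:
                per_cond[cond] = [float(rng.uniform(0.0, 0.9)) for _ in range(cfg.n_replicates)]
        values[g.gene_id] = per_cond
    return ExpressionTable(values=values, conditions=conditions), expressed


def make_erna_counts(
    cfg: LandscapeConfig, loci: Sequence[ErnaLocus]
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-condition per-replicate count table with planted fold changes.

    Counts are drawn from a gamma-Poisson (negative-binomial-like) model
    around ``mean = true_RPKM x length_kb x library_millions``. An exact
    fraction of loci is planted at zero expression; ``n_erna_de`` loci get
    the configured signed fold changes (knockdown/control convention);
    everything else is null (true FC = 1). Returns the count table and the
    truth manifest entries.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    ctrl, kd = cfg.conditions
    n = len(loci)
    n_zero = _exact_count(cfg.erna_zero_frac, n)
    zero_idx = set(rng.choice(n, size=n_zero, replace=False).tolist())
    remaining = [i for i in range(n) if i not in zero_idx]
    if cfg.n_erna_de > len(remaining):
        raise ValueError("more planted DE loci requested than non-zero loci available")
    de_pick = rng.choice(len(remaining), size=cfg.n_erna_de, replace=False)
    de_idx = {remaining[int(j)]: cfg.planted_fc[k % len(cfg.planted_fc)]
              for k, j in enumerate(sorted(de_pick))}

    truth: dict[str, dict] = {}
    rows = []
    for i, locus in enumerate(loci):
        if i in zero_idx:
            r_ctrl = r_kd = 0.0
            fc = None
        else:
            r_ctrl = float(cfg.erna_base_rpkm * np.exp(rng.normal(0.0, 0.2)))
            fc = de_idx.get(i, 1.0)
            r_kd = r_ctrl * fc if fc >= 1 else r_ctrl / (-fc)
        truth[locus.key] = {
            "rpkm": {ctrl: r_ctrl, kd: r_kd},
            "fc": fc,
            "planted_de": i in de_idx,
        }
        row = {"locus": locus.key}
        for cond, true_r in ((ctrl, r_ctrl), (kd, r_kd)):
            mean = true_r * (len(locus.locus) / 1e3) * (cfg.library_size / 1e6)
            for k in range(1, cfg.n_replicates + 1):
                if mean == 0:
                    c = 0
                elif cfg.dispersion > 0:
                    lam = rng.gamma(1.0 / cfg.dispersion, mean * cfg.dispersion)
                    c = int(rng.poisson(lam))
                else:
                    c = int(rng.poisson(mean))
                row[f"{cond}_rep{k}"] = c
        rows.append(row)
    counts = pd.DataFrame(rows).set_index("locus") if rows else pd.DataFrame()
    return counts, truth


def generate(cfg: LandscapeConfig) -> Landscape:
    """Genome + landscape + eRNA truth in one call."""
    genes = make_genome(cfg)
    landscape = make_landscape(cfg, genes)
    exons = [e for g in genes for e in g.exons]
    loci = identify_erna_loci(landscape.h3k27ac_intervals, landscape.h3k4me1, exons)
    counts, truth = make_erna_counts(cfg, loci)
    landscape.manifest.erna_truth = truth
    landscape.erna_loci = loci  # type: ignore[attr-defined]
    landscape.erna_counts = counts  # type: ignore[attr-defined]
    return landscape


def write_fixture(landscape: Landscape, outdir) -> dict[str, Path]:
    """Write the landscape as plain-text files every CLI stage can read.

    Re-reading the files through :mod:`sekit.io` reproduces the in-memory
    objects. Returns the path of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = landscape.config
    paths = {
        "gtf": outdir / "genes.gtf",
        "h3k27ac": outdir / "h3k27ac.narrowPeak",
        "h3k4me1": outdir / "h3k4me1.bed",
        "factor": outdir / "factor.bed",
        "repressive": outdir / "repressive.bed",
        "coverage": outdir / "h3k27ac.bedgraph",
        "control": outdir / "control.bedgraph",
        "expression": outdir / "expression.tsv",
        "erna_counts": outdir / "erna_counts.tsv",
        "manifest": outdir / "manifest.json",
        "config": outdir / "config.json",
    }
    write_gtf(landscape.genes, paths["gtf"])
    write_narrowpeak(landscape.h3k27ac, paths["h3k27ac"])
    write_bed(landscape.h3k4me1, paths["h3k4me1"])
    write_bed(landscape.factor, paths["factor"])
    write_bed(landscape.repressive, paths["repressive"])
    write_bedgraph(landscape.track, paths["coverage"], omit_zero=False)
    write_bedgraph(landscape.control_track, paths["control"], omit_zero=False)
    write_expression(landscape.expression, paths["expression"])
    counts = getattr(landscape, "erna_counts", None)
    if counts is not None:
        counts.to_csv(paths["erna_counts"], sep="\t")
    landscape.manifest.to_json(paths["manifest"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
    return paths
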