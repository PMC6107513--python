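"""End-to-end orchestration: filter -> annotate -> se-call -> se-targets ->
cooccupancy -> erna.

Stages communicate via files in standard formats so any stage can be
re-parsed or replaced by an external tool for cross-validation. Re-running
on identical inputs and config is byte-identical (the summary JSON is
written with sorted keys and no timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotate import annotate_peaks, distribution_summary
from .config import RunConfig
from .cooccupancy import fraction_regions_bound, multi_mark_fraction
from .erna import (
    call_differential,
    classify_by_enhancer,
    identify_erna_loci,
    loci_to_frame,
    quantify,
)
from .intervals import IntervalSet
from .io import (
    filter_peaks,
    read_bed,
    read_bedgraph,
    read_expression,
    read_gtf,
    read_narrowpeak,
    write_bed,
)
from .superenhancer import (
    assign_se_targets,
    build_stitched_enhancers,
    classify,
    expressed_genes,
    se_cutoff,
)

log = logging.getLogger("sekit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the summary dict (also written to
    ``<outdir>/summary.json``).

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained next to a ``FAILED`` marker file.
    """
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
    }
    stage = "setup"
    try:
        # ---------------- filter
        stage = "filter"
        log.info("stage filter: %s", config.h3k27ac_narrowpeak)
        raw_peaks = read_narrowpeak(config.h3k27ac_narrowpeak, label="h3k27ac")
        peaks = filter_peaks(raw_peaks, config.min_fold, config.max_q)
        write_bed(peaks, outdir / "filtered_peaks.bed")
        summary["n_peaks_input"] = len(raw_peaks)
        summary["n_peaks_filtered"] = len(peaks)

        # ---------------- annotate
        stage = "annotate"
        genes = read_gtf(config.gtf)
        factor: Optional[IntervalSet] = (
            read_bed(config.factor_bed, label="factor") if config.factor_bed else None
        )
        to_annotate = factor if factor is not None else peaks
        annotated = annotate_peaks(to_annotate, genes, config.promoter_upstream_bp)
        pd.DataFrame(
            {
                "peak": [str(a.peak) for a in annotated],
                "category": [a.category for a in annotated],
                "gene": [a.assigned_gene or "." for a in annotated],
                "distance_to_tss": [
                    a.distance_to_tss if a.distance_to_tss is not None else "."
                    for a in annotated
                ],
            }
        ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        summary["annotation_fractions"] = distribution_summary(annotated)

        # ---------------- se-call
        stage = "se-call"
        track = read_bedgraph(config.coverage_bedgraph, config.chip_library_size)
        control = (
            read_bedgraph(config.control_bedgraph, config.control_library_size)
            if config.control_bedgraph
            else None
        )
        regions = build_stitched_enhancers(peaks, track, control, config.stitch_distance_bp)
        supers, typicals = classify(regions)
        cutoff = se_cutoff([r.signal for r in regions]) if len(regions) >= 3 else 1.0
        ranked = sorted(regions, key=lambda r: r.rank)
        pd.DataFrame(
            {
                "region": [str(r.region) for r in ranked],
                "rank": [r.rank for r in ranked],
                "n_constituents": [r.n_constituents for r in ranked],
                "signal": [r.signal for r in ranked],
                "scaled_rank": [r.scaled_rank for r in ranked],
                "scaled_signal": [r.scaled_signal for r in ranked],
                "is_super": [r.is_super for r in ranked],
            }
        ).to_csv(outdir / "ranked_enhancers.tsv", sep="\t", index=False)
        se_set = IntervalSet(
            [r.region for r in supers], label="super_enhancers"
        )
        te_set = IntervalSet(
            [r.region for r in typicals], label="typical_enhancers"
        )
        write_bed(se_set, outdir / "super_enhancers.bed")
        write_bed(te_set, outdir / "typical_enhancers.bed")
        summary["n_stitched_regions"] = len(regions)
        summary["n_super_enhancers"] = len(supers)
        summary["n_typical_enhancers"] = len(typicals)
        summary["se_cutoff_scaled"] = cutoff

        # ---------------- se-targets
        stage = "se-targets"
        expr = read_expression(config.expression_tsv)
        expressed = expressed_genes(expr, genes, config.fpkm_min)
        assignments = assign_se_targets(supers, genes, expressed, config.max_target_dist_bp)
        rows = [
            {"se": str(a.se.region), "gene": gid, "distance": dist}
            for a in assignments
            for gid, dist in a.genes
        ]
        pd.DataFrame(rows, columns=["se", "gene", "distance"]).to_csv(
            outdir / "se_targets.tsv", sep="\t", index=False
        )
        summary["n_expressed_genes"] = len(expressed)
        summary["n_se_target_genes"] = len({r["gene"] for r in rows})

        # ---------------- cooccupancy
        stage = "cooccupancy"
        cooc: dict = {}
        if factor is not None:
            if len(se_set):
                cooc["fraction_se_bound"] = fraction_regions_bound(se_set, factor).fraction
            if len(te_set):
                cooc["fraction_te_bound"] = fraction_regions_bound(te_set, factor).fraction
            if config.repressive_bed:
                marks = read_bed(config.repressive_bed, label="repressive")
                fractions = multi_mark_fraction(factor, [marks])
                cooc["fraction_factor_with_repressive"] = fractions[frozenset({"repressive"})]
        summary["cooccupancy"] = cooc
        with open(outdir / "cooccupancy.json", "w") as fh:
            json.dump(cooc, fh, indent=1, sort_keys=True)

        # ---------------- erna
        stage = "erna"
        h3k4me1 = read_bed(config.h3k4me1_bed, label="h3k4me1")
        exons = [e for g in genes for e in g.exons]
        loci = identify_erna_loci(
            peaks,
            h3k4me1,
            exons,
            config.pair_window_bp,
            config.exon_pad_bp,
            config.half_width_bp,
        )
        counts = pd.read_csv(config.erna_counts_tsv, sep="\t", index_col="locus")
        quantify(loci, counts, config.rna_library_sizes)
        call_differential(
            loci,
            config.condition_control,
            config.condition_knockdown,
            config.rpkm_min,
            config.fc_min,
        )
        classify_by_enhancer(loci, se_set, te_set)
        loci_to_frame(loci).to_csv(outdir / "erna_loci.tsv", sep="\t", index=False)
        write_bed(
            [l.locus for l in loci if l.is_differential],
            outdir / "erna_differential.bed",
        )
        summary["n_erna_loci"] = len(loci)
        summary["n_erna_expressed"] = sum(l.expressed for l in loci)
        summary["n_erna_differential"] = sum(l.is_differential for l in loci)
        summary["n_erna_differential_in_se"] = sum(
            l.is_differential and l.enhancer_class == "super" for l in loci
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
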