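"""Run configuration: every input path and every numeric threshold.

Defaults are the analysis constants: MACS peak filter (fold > 4,
q < 0.05), ROSE stitch distance 12.5 kb, promoter window 2.5 kb, eRNA pair
window ±200 bp, exon pad 2 kb, locus half-width 600 bp, expression gates
FPKM > 1 and RPKM > 0.3, fold-change cutoff ±2, SE target cap ±200 kb.
Every value is serialized into the run summary, so no output number depends
on a hidden constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    # input paths
    h3k27ac_narrowpeak: str = ""
    h3k4me1_bed: str = ""
    gtf: str = ""
    coverage_bedgraph: str = ""
    expression_tsv: str = ""
    erna_counts_tsv: str = ""
    factor_bed: Optional[str] = None
    repressive_bed: Optional[str] = None
    control_bedgraph: Optional[str] = None
    # library sizes
    chip_library_size: Optional[int] = None
    control_library_size: Optional[int] = None
    rna_library_sizes: dict = field(default_factory=dict)  # condition -> [per-replicate]
    # condition labels
    condition_control: str = "shCTR"
    condition_knockdown: str = "shKD"
    # thresholds
    min_fold: float = 4.0
    max_q: float = 0.05
    stitch_distance_bp: int = 12_500
    promoter_upstream_bp: int = 2_500
    pair_window_bp: int = 200
    exon_pad_bp: int = 2_000
    half_width_bp: int = 600
    rpkm_min: float = 0.3
    fc_min: float = 2.0
    fpkm_min: float = 1.0
    max_target_dist_bp: int = 200_000
    # run
    seed: int = 1
    outdir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        """Required and optional input files actually configured."""
        required = {
            "h3k27ac_narrowpeak": self.h3k27ac_narrowpeak,
            "h3k4me1_bed": self.h3k4me1_bed,
            "gtf": self.gtf,
            "coverage_bedgraph": self.coverage_bedgraph,
            "expression_tsv": self.expression_tsv,
            "erna_counts_tsv": self.erna_counts_tsv,
        }
        optional = {
            "factor_bed": self.factor_bed,
            "repressive_bed": self.repressive_bed,
            "control_bedgraph": self.control_bedgraph,
        }
        paths = dict(required)
        paths.update({k: v for k, v in optional.items() if v})
        return paths

    def validate_inputs(self) -> None:
        missing = {
            name: p for name, p in self.input_paths().items() if not Path(p).is_file()
        }
        if missing:
            listing = ", ".join(f"{k}={v!r}" for k, v in sorted(missing.items()))
            raise FileNotFoundError(f"missing input file(s): {listing}")
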