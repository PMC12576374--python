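"""Pipeline configuration: every numeric threshold in one place.

Defaults are the study's operating values: CpG calls need >= 5 reads,
feature means need >= 3 covered CpGs, a gene is "methylated" at mean
level >= 10% and "expressed" at FPKM > 1, DMRs need >= 10 CpGs, a >= 10
percentage-point mean difference and BH q < 0.05 computed from CpGs
with coverage in [5, 100] across all replicates, peak calling keeps the
top 2.5% of blocks by AUC, metagene profiles scale gene bodies to 5 kb
with 3 kb flanks at 50 bp bins (0.5 kb flanks for anchored TSS/TES
windows), and GO reporting keeps the 40 most significant terms.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # methylome
    min_coverage: int = 5
    min_cpgs: int = 3
    meth_threshold: float = 10.0
    high_meth_threshold: float = 70.0
    merge_cpg_dyads: bool = False
    gene_methylation_span: str = "gene"  # "gene" (exons+introns) or "exons"
    # expression
    fpkm_threshold: float = 1.0
    fpkm_summary: str = "mean"  # or "median"
    qc_correlation_floor: float = 0.8
    excluded_replicates: list[str] = field(default_factory=list)
    # dmr
    dmr_min_cpgs: int = 10
    dmr_min_diff: float = 10.0
    dmr_alpha: float = 0.05
    dmr_cov_min: int = 5
    dmr_cov_max: int = 100
    dmr_max_gap: int = 300
    # chromatin
    peak_fraction: float = 0.025
    # profiles
    profile_body: int = 5000
    profile_flank: int = 3000
    profile_bin: int = 50
    anchored_flank: int = 500
    mask_flank_genes: bool = False
    # go
    go_top_n: int = 40
    go_alpha: float = 0.05
    # misc
    chrom_aliases: dict[str, str] = field(default_factory=dict)
    control_chroms: list[str] = field(default_factory=lambda: ["Lambda", "pUC19"])
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "min_coverage": self.min_coverage,
            "min_cpgs": self.min_cpgs,
            "meth_threshold": self.meth_threshold,
            "fpkm_threshold": self.fpkm_threshold,
            "dmr_min_cpgs": self.dmr_min_cpgs,
            "dmr_min_diff": self.dmr_min_diff,
            "dmr_alpha": self.dmr_alpha,
            "profile_body": self.profile_body,
            "profile_flank": self.profile_flank,
            "profile_bin": self.profile_bin,
            "anchored_flank": self.anchored_flank,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config: {name} must be positive, got {value}")
        if not (0 < self.peak_fraction <= 1):
            raise ValueError(
                f"config: peak_fraction must be in (0, 1], got {self.peak_fraction}"
            )
        if not (0 < self.dmr_alpha < 1):
            raise ValueError(f"config: dmr_alpha must be in (0, 1)")
        if self.dmr_cov_min > self.dmr_cov_max:
            raise ValueError("config: dmr_cov_min > dmr_cov_max")
        if self.gene_methylation_span not in ("gene", "exons"):
            raise ValueError("config: gene_methylation_span must be 'gene' or 'exons'")
        if self.fpkm_summary not in ("mean", "median"):
            raise ValueError("config: fpkm_summary must be 'mean' or 'median'")
        if self.go_top_n < 0:
            raise ValueError("config: go_top_n must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
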