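"""Pipeline configuration: every tunable with its documented default."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input paths (optional when driving the pipeline from the simulator)
    genotypes_vcf: str | None = None
    phenotype_tsv: str | None = None
    annotation_gff3: str | None = None
    expression_tsv: str | None = None

    populations: tuple[str, ...] = ("Full", "Ind", "Jap")
    trait: str = "TFC"

    # SNP QC
    max_missing: float = 0.30
    min_maf: float = 0.05
    # LD pruning (PLINK-style SNP-count windows)
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.3
    # structure / model
    n_pcs: int = 3
    # permutation threshold
    n_perm: int = 1000
    quantile: float = 0.95
    # QTL calling
    min_run: int = 3
    max_gap: int = 170_000
    # candidate screening
    r2_min: float = 0.6
    flank: int = 1_000_000
    promoter_len: int = 2000
    min_group_n: int = 10
    alpha: float = 0.05
    min_expr_class: str = "moderate"

    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.max_missing <= 1, "max_missing in [0,1]"),
            (0 <= self.min_maf <= 0.5, "min_maf in [0,0.5]"),
            (self.prune_window >= self.prune_step >= 1, "window >= step >= 1"),
            (0 < self.prune_r2 <= 1, "prune_r2 in (0,1]"),
            (self.n_pcs >= 0, "n_pcs >= 0"),
            (self.n_perm >= 20, "n_perm >= 20"),
            (0 < self.quantile <= 1, "quantile in (0,1]"),
            (self.min_run >= 1, "min_run >= 1"),
            (self.max_gap > 0, "max_gap > 0"),
            (0 < self.r2_min <= 1, "r2_min in (0,1]"),
            (self.flank > 0, "flank > 0"),
            (self.promoter_len >= 0, "promoter_len >= 0"),
            (self.min_group_n >= 1, "min_group_n >= 1"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: {msg}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["populations"] = list(self.populations)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "populations" in d:
            d["populations"] = tuple(d["populations"])
        return cls(**d)
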