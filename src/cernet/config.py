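"""Pipeline configuration: every tunable threshold in one dataclass.

Defaults follow the study design the pipeline implements: hypergeometric
shared-miRNA test at p < 0.01; control-sample Pearson correlations > 0.7
(lncRNA-mRNA) and < -0.7 (miRNA-mRNA, miRNA-lncRNA) each at p < 0.05;
SDE calls at p < 0.01 and |log2FC| > 1.2; permutation significance at
empirical p < 0.05; initial TO-BCeN nodes from the bottom decile of node
dysregulation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datatypes import COUNT_FILTER_MIN_READS


@dataclass
class PipelineConfig:
    hyper_p: float = 0.01          # shared-miRNA hypergeometric cut-off
    pcc_pos: float = 0.7           # lncRNA-mRNA correlation floor
    pcc_neg: float = -0.7          # miRNA-mRNA / miRNA-lncRNA ceiling
    pcc_p: float = 0.05            # two-sided correlation p cut-off
    sde_p: float = 0.01            # SDE p cut-off
    sde_fc: float = 1.2            # SDE |log2FC| cut-off (strict >)
    n_perm: int = 1000             # permutations for empirical p
    dysreg_p: float = 0.05         # empirical-p cut-off for "dysregulated"
    initial_decile: float = 0.10   # bottom score fraction for initial nodes
    n_initial: int = 2             # number of initial nodes
    count_filter: dict = field(default_factory=lambda: dict(COUNT_FILTER_MIN_READS))
    prevalence: float = 0.5        # gene kept iff prevalence strictly exceeds this
    rng_seed: int = 0
    shuffle_mode: str = "shared"   # "shared" or "per_rna" permutation scheme

    def __post_init__(self) -> None:
        for name in ("hyper_p", "pcc_p", "sde_p", "dysreg_p", "initial_decile", "prevalence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")
        if not -1.0 < self.pcc_neg < 0.0 < self.pcc_pos < 1.0:
            raise ValueError("correlation thresholds must satisfy -1 < pcc_neg < 0 < pcc_pos < 1")
        if self.shuffle_mode not in ("shared", "per_rna"):
            raise ValueError(f"shuffle_mode must be shared|per_rna, got {self.shuffle_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
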