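"""Scan configuration.

All thresholds of the pipeline live in one flat record so a run is fully
described by (inputs, config, seed).  Defaults follow the yeast segregant
analysis the method was developed on: expression is rank-transformed to
normal quantiles (SD ~ 0.97 at n = 109, hence the fixed model SD), each
joint genotype class must hold at least 15 segregants, neighbouring
markers with fewer than 5 discordant calls are merged before the scan and
with fewer than 15 after it, and ten expression permutations estimate the
FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["ScanConfig"]


@dataclass
class ScanConfig:
    #: fixed standard deviation of both traits in the bivariate model
    sd_fixed: float = 0.97
    #: PA (Potential of Association) pre-filter cutoff
    pa_cutoff: float = 45.0
    #: minimum samples per joint-genotype class for a marker pair
    min_class_size: int = 15
    #: genes with more missing values than this are dropped
    max_missing_per_gene: int = 10
    #: pre-scan marker merge: merge neighbours with fewer discordant calls
    marker_merge_discordance: int = 5
    #: post-scan module merge threshold
    module_merge_discordance: int = 15
    #: LR-test p-value cutoff declaring a module significant
    p_threshold: float = 1e-6
    #: single-trait (Wilcoxon) linkage cutoff for the 1D filter
    oned_p_threshold: float = 1e-5
    #: epistasis-versus-marginal test cutoff
    epistasis_p_threshold: float = 0.05
    #: number of expression permutations for FDR estimation
    n_permutations: int = 10
    #: master seed for every stochastic step
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_fixed", "min_class_size", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("pa_cutoff", "max_missing_per_gene",
                     "marker_merge_discordance", "module_merge_discordance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_threshold", "oned_p_threshold", "epistasis_p_threshold"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "ScanConfig":
        data = self.to_dict()
        data.update(kwargs)
        return ScanConfig(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
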