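"""Pipeline configuration: every analysis threshold in one serializable place.

The defaults are the thresholds the analyses are defined around:
ΔPSI call/stringent cutoffs of 5% and 20% at FDR 0.05 for differential
exon inclusion, top/bottom 10% expression deciles, a 35% max-|ΔPSI| filter
and a 450-sample cohort minimum for the cross-cancer matrix, 10 informative
junction reads for a PSI value to be reported, and α = 0.05 for clinical
correlation significance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["Thresholds", "PipelineConfig"]


@dataclass
class Thresholds:
    delta_psi_call: float = 0.05
    delta_psi_stringent: float = 0.20
    fdr: float = 0.05
    decile_fraction: float = 0.10
    cross_cancer_min_delta: float = 0.35
    min_samples_per_cancer: int = 450
    min_coverage: int = 10
    clinical_alpha: float = 0.05
    min_group_n: int = 10
    constitutive_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in ("delta_psi_call", "delta_psi_stringent", "fdr",
                     "cross_cancer_min_delta", "clinical_alpha",
                     "constitutive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.decile_fraction <= 0.5:
            raise ValueError(f"decile_fraction={self.decile_fraction} outside (0, 0.5]")
        if self.min_samples_per_cancer < 1 or self.min_coverage < 0 or self.min_group_n < 1:
            raise ValueError("count thresholds must be positive")


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (thresholds + paths + seed)."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "paths": dict(self.paths),
            "seed": int(self.seed),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(
            thresholds=Thresholds(**d.get("thresholds", {})),
            paths=dict(d.get("paths", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
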