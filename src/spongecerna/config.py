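"""Run configuration: the thresholds every pipeline stage consumes.

All thresholds default to the values used throughout the analysis:
FDR < 0.01 and |log2FC| > 1 for differential expression, at least three
shared miRNAs (M > 2) at hypergeometric p < 0.01 for sponge candidacy,
BH-adjusted correlation p < 0.05, the top 20% of lncRNAs by degree as
hubs, log-rank p < 0.01 for the survival screen and a white-blood-cell
count of 50 (x10^9/L) for risk stratification.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    de_fdr: float = 0.01
    de_lfc: float = 1.0
    sponge_min_shared: int = 3
    sponge_p: float = 0.01
    corr_adj_p: float = 0.05
    hub_fraction: float = 0.20
    survival_p: float = 0.01
    survival_hr: float = 2.0
    causal_adj_p: float = 0.05
    wbc_cutoff: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "sponge_p", "corr_adj_p", "survival_p", "causal_adj_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.hub_fraction < 1.0 or self.hub_fraction == 0:
            if not 0.0 < self.hub_fraction <= 1.0:
                raise ValueError(f"hub_fraction must be in (0, 1], got {self.hub_fraction}")
        if self.sponge_min_shared < 1:
            raise ValueError(f"sponge_min_shared must be >= 1, got {self.sponge_min_shared}")
        if self.de_lfc < 0:
            raise ValueError(f"de_lfc must be >= 0, got {self.de_lfc}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML file whose keys mirror the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
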