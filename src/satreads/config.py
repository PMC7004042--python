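"""Run configuration: every pipeline threshold, with study defaults.

A :class:`RunConfig` built with no overrides reproduces the analysis
settings of the worked example: 30-kb read floor, 7000 bit-score hit
filter, 1.23x reference-length cap, 300/500-bp array minima, 5-kb
histogram bins pooling above 120 kb, 10-kb flank windows with a 0.05
report threshold, 30-kb periodicity floor, autocorrelation lags 2-2000,
and the five protein-domain quality cutoffs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


def _default_min_array() -> dict[str, int]:
    return {"satellite": 300, "rDNA": 500, "telomere": 500}


@dataclass
class RunConfig:
    min_read_length: int = 30_000
    min_score: float = 7_000.0
    max_length_ratio: float = 1.23
    min_array_length: dict[str, int] = field(default_factory=_default_min_array)
    max_gap: int = 0
    edge_tolerance: int = 100
    histogram_bin: int = 5_000
    histogram_last_bin: int = 120_000
    flank_window: int = 10_000
    report_threshold: float = 0.05
    periodicity_min_array: int = 30_000
    autocorr_min_lag: int = 2
    autocorr_max_lag: int = 2_000
    domain_min_identity: float = 0.3
    domain_min_similarity: float = 0.4
    domain_min_aln_length: float = 0.7
    domain_max_interruptions: int = 10
    domain_max_length_proportion: float = 1.2
    hit_dialect: str = "lastz-general"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_read_length < 0 or self.min_score < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_length_ratio <= 0:
            raise ValueError("max_length_ratio must be positive")
        for cls, value in self.min_array_length.items():
            if value < 0:
                raise ValueError(f"min_array_length[{cls}] must be >= 0")
        if self.histogram_bin <= 0 or self.flank_window <= 0:
            raise ValueError("bin and window sizes must be positive")
        if not 0 <= self.report_threshold <= 1:
            raise ValueError("report_threshold must be in [0, 1]")
        if not 1 <= self.autocorr_min_lag <= self.autocorr_max_lag:
            raise ValueError("bad autocorrelation lag range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
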