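"""Pipeline configuration: every numeric constant in one place.

Defaults are the trial's printed values: the 0.3 mg/dL / 1.5x detection
thresholds, the 2.0x and 3.0x staging ratios and the 4.0 mg/dL stage-3
rule, the eGFR 15 and SCr 0.5 eligibility floors, the 48 h / 7 d rolling
windows, the 2/3/7/28/90-day outcome horizons, the universal randomization
seed 20180101, and the 95% confidence level.  Configurations round-trip
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synth import GeneratorConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # detection / staging thresholds (mg/dL and ratios)
    delta_threshold: float = 0.3
    ratio_threshold: float = 1.5
    stage2_ratio: float = 2.0
    stage3_ratio: float = 3.0
    stage3_scr: float = 4.0
    stage3_scr_rule: str = "value"  # "value" or "delta"
    # eligibility floors
    egfr_floor: float = 15.0
    scr_floor: float = 0.5
    min_stay_h: float = 24.0
    # windows, hours
    delta_window_h: float = 48.0
    baseline_window_h: float = 168.0
    care_window_h: float = 48.0
    toxin3_window_h: float = 72.0
    outcome_window_h: float = 168.0
    day28_h: float = 672.0
    day90_h: float = 2160.0
    # randomization & analysis
    universal_seed: int = 20180101
    block_size: int = 0  # 0 = simple Bernoulli 1:1
    ci_level: float = 0.95
    recovery_ratio: float = 1.5
    egfr_variant: str = "2009"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        positives = [
            self.delta_threshold, self.ratio_threshold, self.stage2_ratio,
            self.stage3_ratio, self.stage3_scr, self.egfr_floor, self.scr_floor,
            self.min_stay_h, self.delta_window_h, self.baseline_window_h,
            self.care_window_h, self.toxin3_window_h, self.outcome_window_h,
            self.day28_h, self.day90_h,
        ]
        if any(v <= 0 for v in positives):
            raise ValueError("thresholds and windows must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)
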