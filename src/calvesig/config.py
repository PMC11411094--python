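"""Pipeline configuration: one flat, strictly validated record of every
stage parameter, round-trippable through YAML.

All randomness in a run flows from the single ``seed``; stage-local
generators are derived from it deterministically.  Unknown keys in a config
file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class PipelineConfig:
    # identification
    subject_id: str = "synthetic"
    calving_time_h: Optional[float] = None   # hours from recording start
    # preprocess
    outlier_threshold: float = 0.30
    outlier_window: int = 60
    bin_width_h: float = 0.5
    min_beats: int = 30
    max_gap_bins: int = 48
    # decomposition
    period: int = 48
    seasonal_window: object = "periodic"     # "periodic" or odd int
    trend_window: Optional[int] = None
    robust: bool = False
    trend_method: str = "stl"                # "stl" or "loess"
    loess_span: float = 0.75
    loess_degree: int = 2
    # indicators
    sma_n: int = 12
    mad_n: int = 12
    mad_mode: str = "percent"
    macd_short: int = 12
    macd_long: int = 26
    macd_mode: str = "percent"
    rsi_n: int = 14
    rsi_smoothing: str = "simple"
    # detection
    detector: str = "retrospective"          # or "online"
    online_k: int = 3
    # comparison
    exclude_incomplete: bool = True
    # randomness
    seed: int = 0

    def validate(self) -> None:
        if self.macd_short >= self.macd_long:
            raise ConfigError(
                f"macd_short ({self.macd_short}) must be < macd_long "
                f"({self.macd_long})"
            )
        if not 0 < self.outlier_threshold < 1:
            raise ConfigError("outlier_threshold must be in (0, 1)")
        if self.bin_width_h <= 0:
            raise ConfigError("bin_width_h must be positive")
        if self.trend_method not in ("stl", "loess"):
            raise ConfigError("trend_method must be 'stl' or 'loess'")
        if self.detector not in ("retrospective", "online"):
            raise ConfigError("detector must be 'retrospective' or 'online'")
        if self.mad_mode not in ("percent", "difference"):
            raise ConfigError("mad_mode must be 'percent' or 'difference'")
        if self.macd_mode not in ("percent", "difference"):
            raise ConfigError("macd_mode must be 'percent' or 'difference'")
        for name in ("sma_n", "mad_n", "macd_short", "rsi_n", "online_k",
                     "outlier_window", "period"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {unknown}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg
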