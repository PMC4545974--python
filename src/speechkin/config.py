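"""Run configuration: one declarative object covering every stage.

Defaults follow the analysis conventions documented per module: 10 Hz
zero-phase Butterworth smoothing, 0.10 relative peak prominence, syllable
cycles Bob -> 2 and pup -> 4, 7-10 trials per participant, 80% dynamic-range
coverage, 1000-point / 50-point LA normalization grid, and a 3-SD normative
exclusion screen (disabled unless normative values are supplied).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class FilterConfig:
    cutoff_hz: float = 10.0
    order: int = 4


@dataclass
class SegmentationConfig:
    prominence_frac: float = 0.10
    # syllable label -> 1-based opening-cycle ordinal within the sentence
    cycles: dict[str, int] = field(default_factory=lambda: {"Bob": 2, "pup": 4})


@dataclass
class AnalysisConfig:
    min_trials: int = 7
    max_trials: int = 10


@dataclass
class DynamicRangeConfig:
    coverage: float = 0.8


@dataclass
class StiConfig:
    n_points: int = 1000
    n_grid: int = 50
    include_start: bool = False
    sd_ddof: int = 1


@dataclass
class ExclusionConfig:
    # measure name -> [normative mean, normative sd]; empty disables screening
    normative: dict[str, tuple[float, float]] = field(default_factory=dict)
    k_sd: float = 3.0


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Aggregated configuration for a full pipeline run."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    dynamic_range: DynamicRangeConfig = field(default_factory=DynamicRangeConfig)
    sti: StiConfig = field(default_factory=StiConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    head_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.segmentation.prominence_frac < 1:
            raise ParameterError("segmentation.prominence_frac must be in (0, 1)")
        if not 0 < self.dynamic_range.coverage < 1:
            raise ParameterError("dynamic_range.coverage must be in (0, 1)")
        if self.analysis.min_trials < 2:
            raise ParameterError("analysis.min_trials must be >= 2")
        if self.analysis.max_trials < self.analysis.min_trials:
            raise ParameterError("analysis.max_trials must be >= min_trials")
        if self.sti.n_points % self.sti.n_grid != 0:
            raise ParameterError("sti.n_points must be a multiple of sti.n_grid")
        if self.filter.cutoff_hz <= 0:
            raise ParameterError("filter.cutoff_hz must be positive")
        if not 0 < self.stats.alpha < 1:
            raise ParameterError("stats.alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sections = {
            "filter": FilterConfig,
            "segmentation": SegmentationConfig,
            "analysis": AnalysisConfig,
            "dynamic_range": DynamicRangeConfig,
            "sti": StiConfig,
            "exclusion": ExclusionConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, value in d.items():
            if key in sections:
                kwargs[key] = sections[key](**value)
            elif key in ("head_correction", "seed"):
                kwargs[key] = value
            else:
                raise ParameterError(f"unknown config key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
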