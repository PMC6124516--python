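"""Pipeline configuration with the study's calling thresholds as defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Thresholds, paths and the simulation settings for a pipeline run.

    Every analysis threshold defaults to the study's printed value:
    minimum mean normalised count 10, fold-change 1.10, adjusted-P 0.01,
    CpG coverage 10x, minimum 4 CpGs per promoter, promoter flank
    1,000 bp, top-10 screen candidates, validation P 0.01.
    """

    # expression-bias thresholds
    min_mean_count: float = 10.0
    fc_threshold: float = 1.10
    adjusted_p: float = 0.01
    # methylation thresholds
    min_cpg_coverage: int = 10
    min_cpgs: int = 4
    promoter_flank: int = 1000
    meth_consistency_threshold: float = 0.1
    # metabolite screen
    top_k: int = 10
    validation_p: float = 0.01
    screen_visits: tuple[int, ...] = (12, 20, 28)
    validation_visit: int = 36
    metabolite_transform: str = "log"  # log | identity | sqrt
    # cross-tissue comparison
    n_comparison_tissues: int = 19
    # orchestration
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screen_visits"] = list(self.screen_visits)
        d["simulation"]["visit_schedule"] = list(
            self.simulation.visit_schedule)
        d["simulation"]["baseline_mean_range"] = list(
            self.simulation.baseline_mean_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if sim:
            sim = dict(sim)
            if "visit_schedule" in sim:
                sim["visit_schedule"] = tuple(sim["visit_schedule"])
            if "baseline_mean_range" in sim:
                sim["baseline_mean_range"] = tuple(sim["baseline_mean_range"])
        if "screen_visits" in d:
            d["screen_visits"] = tuple(d["screen_visits"])
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
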