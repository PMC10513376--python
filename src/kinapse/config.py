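"""Pipeline configuration: one YAML file, one root seed, logged overrides."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import yaml

from kinapse.features import COAST_THRESHOLD, WindowSpec
from kinapse.model import ForestConfig, GroupedCVSpec
from kinapse.synthetic import SimConfig
from kinapse.track_io import DialectConfig

logger = logging.getLogger(__name__)


@dataclass
class MRMRConfig:
    scheme: str = "quotient"
    grid_start: int = 3
    grid_step: int = 2
    grid_max: int = 21
    stop_delta: float = 0.005
    stop_horizon: int = 5


@dataclass
class PipelineConfig:
    dialect: DialectConfig = field(default_factory=DialectConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    coast_threshold: float = COAST_THRESHOLD
    mrmr: MRMRConfig = field(default_factory=MRMRConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    cv_forest_n_trees: int = 100   # lighter forest during the feature-count search
    cv: GroupedCVSpec = field(default_factory=GroupedCVSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "dialect" in raw:
            cfg.dialect = DialectConfig.from_dict(raw["dialect"])
        if "window" in raw:
            cfg.window = WindowSpec(**raw["window"])
        if "coast_threshold" in raw:
            cfg.coast_threshold = float(raw["coast_threshold"])
        if "mrmr" in raw:
            cfg.mrmr = MRMRConfig(**raw["mrmr"])
        if "forest" in raw:
            cfg.forest = ForestConfig(**raw["forest"])
        if "cv_forest_n_trees" in raw:
            cfg.cv_forest_n_trees = int(raw["cv_forest_n_trees"])
        if "cv" in raw:
            cfg.cv = GroupedCVSpec(**raw["cv"])
        if "sim" in raw:
            cfg.sim = SimConfig.from_dict(raw["sim"])
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        for key in raw:
            if key not in cls.__dataclass_fields__:
                logger.warning("unknown config key %r ignored", key)
            else:
                logger.info("config override: %s", key)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
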