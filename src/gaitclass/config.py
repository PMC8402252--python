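"""Run configuration: one YAML-serialisable object driving the whole pipeline.

Unknown keys are rejected on load, and every run's effective configuration
is persisted (with its hash) beside the outputs so a stored bundle can be
re-validated against the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .balancing import BALANCING_METHODS
from .embedding import REDUCERS
from .scaling import SCALING_METHODS
from .synthetic import EffectSizes, GaitParams

__all__ = ["RunConfig", "config_hash"]


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
                value = _from_mapping(f.type, value, f.name)
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class CohortConfig:
    n_healthy: int = 20
    n_ataxic: int = 23
    severity_min: float = 0.25
    severity_max: float = 1.0


@dataclass
class PreprocessConfig:
    window_s: float = 0.5
    heading_rate_threshold_deg_s: float = 45.0
    contact_height_fraction: float = 0.1
    speed_threshold: float = 0.05
    min_contacts: int = 4


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    generator: dict = field(default_factory=dict)  # GaitParams overrides
    effect_sizes: dict = field(default_factory=dict)  # EffectSizes overrides
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scaling: str = "zscore"
    balancing: str = "smote"
    balancing_params: dict = field(default_factory=dict)
    reducers: list = field(default_factory=lambda: list(REDUCERS))
    reducer_hyperparams: dict = field(default_factory=dict)
    classifiers: list | None = None  # None = the full ten-classifier registry
    classifier_hyperparams: dict = field(default_factory=dict)
    cv_scheme: str = "holdout_60_40"
    leakage_mode: str = "joint"  # 'joint' (paper-style, optimistic) or 'strict'
    surface_classifiers: list = field(default_factory=lambda: ["Random Forest"])
    surface_reducer: str = "TSNE"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = _from_mapping(CohortConfig, self.cohort, "cohort")
        if isinstance(self.preprocess, dict):
            self.preprocess = _from_mapping(PreprocessConfig, self.preprocess, "preprocess")
        if self.scaling not in SCALING_METHODS:
            raise ValueError(f"scaling must be one of {SCALING_METHODS}")
        if self.balancing not in BALANCING_METHODS:
            raise ValueError(f"balancing must be one of {BALANCING_METHODS}")
        unknown = set(self.reducers) - set(REDUCERS)
        if unknown:
            raise ValueError(f"unknown reducer(s) {sorted(unknown)}")
        if self.leakage_mode not in ("joint", "strict"):
            raise ValueError("leakage_mode must be 'joint' or 'strict'")
        GaitParams(**self.generator).validate()  # reject unknown/invalid overrides
        EffectSizes(**self.effect_sizes)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_mapping(cls, data, "run config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    # -- derived objects ---------------------------------------------------
    def gait_params(self) -> GaitParams:
        return GaitParams(**self.generator)

    def effects(self) -> EffectSizes:
        return EffectSizes(**self.effect_sizes)

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of the config.

    ``out_dir`` is excluded: the hash identifies the scientific
    configuration, not where its outputs land.
    """
    payload = config.to_dict()
    payload.pop("out_dir", None)
    canonical = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
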