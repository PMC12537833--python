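"""Run configuration: YAML-backed, hashable, with per-task defaults.

The three tasks share one schema; when ``features.n_components`` is unset
it defaults to 100 for the craving regression and the cue-type readout and
to 50 for the high/low readout (the extreme-block subset halves the sample
count).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "FeatureSection", "ModelSection", "EvalSection",
           "InferSection", "PathSection"]

TASKS = ("regress", "classify_craving", "classify_cue")

_TASK_COMPONENTS = {"regress": 100, "classify_craving": 50, "classify_cue": 100}


@dataclass(frozen=True)
class FeatureSection:
    method: str = "pca"
    n_components: int | None = None  # None -> task default
    variance_threshold: float = 0.001


@dataclass(frozen=True)
class ModelSection:
    family: str = "ols"
    hyperparameters: dict = field(default_factory=dict)
    grid_enabled: bool = False
    grid_components: tuple[int, ...] = (50, 100)
    grid_families: tuple[str, ...] = ("ols", "ridge", "lasso")


@dataclass(frozen=True)
class EvalSection:
    k: int = 5
    holdout_fraction: float = 0.2
    repetitions: int = 100
    seed: int = 0


@dataclass(frozen=True)
class InferSection:
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    within_subject: bool = False


@dataclass(frozen=True)
class PathSection:
    """Inputs for non-synthetic runs; all None means simulate."""

    volume: str | None = None
    metadata: str | None = None
    mask: str | None = None
    parcellation: str | None = None
    parcellation_names: str | None = None
    atlas_regions: int = 246  # synthetic parcellation size when no atlas given


@dataclass(frozen=True)
class RunConfig:
    task: str = "regress"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    features: FeatureSection = field(default_factory=FeatureSection)
    models: ModelSection = field(default_factory=ModelSection)
    evaluation: EvalSection = field(default_factory=EvalSection)
    inference: InferSection = field(default_factory=InferSection)
    paths: PathSection = field(default_factory=PathSection)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        for p in (self.paths.volume, self.paths.metadata):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")

    @property
    def n_components(self) -> int:
        return self.features.n_components or _TASK_COMPONENTS[self.task]

    @property
    def reducer_config(self) -> dict:
        return {
            "method": self.features.method,
            "n_components": self.n_components,
            "variance_threshold": self.features.variance_threshold,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash stamped onto every run artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})

        def sub(key, klass):
            raw = dict(d.get(key) or {})
            for k in ("rating_thresholds", "grid_components", "grid_families",
                      "inter_block_interval"):
                if k in raw and isinstance(raw[k], list):
                    raw[k] = tuple(raw[k])
            return klass(**raw)

        return cls(
            task=d.get("task", "regress"),
            synthetic=sub("synthetic", SyntheticConfig),
            features=sub("features", FeatureSection),
            models=sub("models", ModelSection),
            evaluation=sub("evaluation", EvalSection),
            inference=sub("inference", InferSection),
            paths=sub("paths", PathSection),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        """Rebase both the generator seed and the evaluation seed."""
        return dataclasses.replace(
            self,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
            evaluation=dataclasses.replace(self.evaluation, seed=seed),
        )
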