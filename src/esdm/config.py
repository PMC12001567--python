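"""Pipeline configuration: YAML in, validated dataclasses out.

Defaults encode the conventional workflow settings — VIF ≤ 5, pairwise
|r| ≤ 0.75, 70/30 train/test split, the GLM/RF/BRT/SVM quartet with 5
replicate splits — and a synthetic virtual-species mode that needs no input
files.  A single global seed is expanded deterministically into per-stage
seeds so one knob reproduces a whole run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .sdm_fit import ALGORITHMS


@dataclass
class SyntheticConfig:
    shape: tuple[int, int] = (100, 100)
    n_presence: int = 150
    autocorr_range: float = 5.0
    species: str = "virtual"


@dataclass
class PathsConfig:
    layers: list[str] = field(default_factory=list)
    layer_names: list[str] | None = None
    occurrences: str | None = None
    species: str | None = None
    crs: str = "geographic"


@dataclass
class VifConfig:
    method: str = "vifstep"  # vifstep | vifcor
    vif_threshold: float = 5.0
    corr_threshold: float = 0.75


@dataclass
class ModelConfig:
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    replicates: int = 5
    train_frac: float = 0.7
    n_background: int | None = None
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class ImportanceConfig:
    n_permutations: int = 10
    n_grid: int = 100


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | files
    output_dir: str = "esdm_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    vif: VifConfig = field(default_factory=VifConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    #: scenario name -> {layer: additive shift} (synthetic mode)
    #: or scenario name -> {"layers": [paths...]} (files mode)
    scenarios: dict = field(default_factory=dict)
    class_boundaries: tuple[float, float] = (1 / 3, 2 / 3)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            if not self.paths.layers:
                raise ConfigError("files mode requires paths.layers")
            if not self.paths.occurrences:
                raise ConfigError("files mode requires paths.occurrences")
            if not self.paths.species:
                raise ConfigError("files mode requires paths.species")
        unknown = [a for a in self.model.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ConfigError(f"unknown algorithm(s) {unknown}; choose from {list(ALGORITHMS)}")
        if len(self.model.algorithms) < 2:
            raise ConfigError("ensemble needs at least 2 algorithms")
        if self.vif.method not in ("vifstep", "vifcor"):
            raise ConfigError(f"vif.method must be 'vifstep' or 'vifcor', got {self.vif.method!r}")
        if not 0 < self.model.train_frac < 1:
            raise ConfigError("model.train_frac must lie strictly between 0 and 1")
        b1, b2 = self.class_boundaries
        if not 0 < b1 < b2 < 1:
            raise ConfigError("class_boundaries must satisfy 0 < b1 < b2 < 1")
        if self.model.replicates < 1:
            raise ConfigError("model.replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["shape"] = list(self.synthetic.shape)
        d["class_boundaries"] = list(self.class_boundaries)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    sub = {
        "synthetic": SyntheticConfig,
        "paths": PathsConfig,
        "vif": VifConfig,
        "model": ModelConfig,
        "importance": ImportanceConfig,
    }
    kwargs: dict = {}
    for key, value in data.items():
        if key in sub:
            kwargs[key] = _build(sub[key], dict(value or {}), key)
        else:
            kwargs[key] = value
    if "synthetic" in kwargs and isinstance(kwargs["synthetic"].shape, list):
        kwargs["synthetic"].shape = tuple(kwargs["synthetic"].shape)
    if "class_boundaries" in kwargs:
        kwargs["class_boundaries"] = tuple(kwargs["class_boundaries"])
    try:
        cfg = _build(PipelineConfig, kwargs, "<root>")
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
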