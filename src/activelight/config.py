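"""YAML/JSON experiment configuration loading and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .control import ControllerParams
from .plant import DiffuserPSF, SceneConfig, TemporalProcesses

SCENARIOS = ("spatial", "temporal_media", "condensation", "instability", "custom")


@dataclass(frozen=True)
class ExperimentConfig:
    """Top-level experiment description, loadable from YAML or JSON."""

    scenario: str = "spatial"
    scene: SceneConfig = field(default_factory=SceneConfig)
    controller: ControllerParams = field(default_factory=ControllerParams)
    days: int = 33
    duration_s: float = 7200.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.scenario == "temporal_media" and self.days < 1:
            raise ValueError("temporal_media requires days >= 1")
        if self.scenario == "condensation" and self.duration_s <= 0:
            raise ValueError("condensation requires a positive duration")


def _build(cls, data: dict):
    """Construct a (frozen) dataclass from a plain dict, recursing into
    nested dataclass fields and rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    nested = {
        "scene": SceneConfig,
        "controller": ControllerParams,
        "diffuser": DiffuserPSF,
        "temporal": TemporalProcesses,
    }
    for k, v in data.items():
        if k in nested and isinstance(v, dict):
            kwargs[k] = _build(nested[k], v)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration file (YAML or JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("experiment config must be a mapping")
    cfg = _build(ExperimentConfig, data)
    if cfg.seed != cfg.scene.seed:
        cfg = dataclasses.replace(cfg, scene=dataclasses.replace(cfg.scene, seed=cfg.seed))
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one experiment run: provenance plus artifact paths."""

    scenario: str
    config_hash: str
    seed: int
    artifacts: list[str] = field(default_factory=list)
    k_m: list[int] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path
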