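"""Run configuration: schema, defaults, validation, YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .glcm import GLCMParams
from .scene import STAGES


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "scene", "glcm", "screening", "models", "mapping"},
    "scene": {"stages", "shape", "params"},
    "glcm": {"window", "levels", "distance", "directions"},
    "screening": {"threshold", "top_vis"},
    "models": {"names", "repeats", "train_frac", "grid_search"},
    "mapping": {"enabled", "model", "feature_set"},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/alfapnc"
    scene: dict = field(default_factory=lambda: {
        "stages": list(STAGES), "shape": [200, 200], "params": {},
    })
    glcm: dict = field(default_factory=lambda: {
        "window": 9, "levels": 64, "distance": 1,
        "directions": [0, 45, 90, 135],
    })
    screening: dict = field(default_factory=lambda: {
        "threshold": 0.5, "top_vis": 3,
    })
    models: dict = field(default_factory=lambda: {
        "names": ["RFR", "SVR", "BPNN", "XGB"],
        "repeats": 10, "train_frac": 2.0 / 3.0, "grid_search": False,
    })
    mapping: dict = field(default_factory=lambda: {
        "enabled": True, "model": "XGB", "feature_set": "VIs+TIs",
    })

    def glcm_params(self) -> GLCMParams:
        g = self.glcm
        return GLCMParams(
            window=int(g["window"]), levels=int(g["levels"]),
            distance=int(g["distance"]),
            directions=tuple(int(d) for d in g["directions"]),
        )

    def scene_config(self) -> dict:
        return {
            "stages": list(self.scene["stages"]),
            "shape": tuple(self.scene["shape"]),
            "params": dict(self.scene.get("params", {})),
        }

    def to_dict(self) -> dict:
        return asdict(self)


def _check_keys(section: str, given: Mapping[str, Any]) -> None:
    unknown = set(given) - _SCHEMA[section]
    if unknown:
        where = section or "top level"
        raise ConfigError(f"unknown {where} config keys: {sorted(unknown)}")


def make_config(data: Mapping[str, Any] | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a plain mapping; unknown keys fail."""
    data = dict(data or {})
    data.update(overrides)
    _check_keys("", data)
    cfg = RunConfig()
    for key in ("seed", "outdir"):
        if key in data:
            setattr(cfg, key, data[key])
    for section in ("scene", "glcm", "screening", "models", "mapping"):
        if section in data:
            sub = dict(data[section])
            _check_keys(section, sub)
            getattr(cfg, section).update(sub)
    for stage in cfg.scene["stages"]:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}; known: {STAGES}")
    cfg.glcm_params()  # validates
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    return make_config(data or {})
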