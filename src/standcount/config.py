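"""Run configuration: YAML/JSON loading, defaults and snapshots."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_scene import SceneParams


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    bands: tuple[str, ...] = ("PAN", "NIR")
    window_sizes: tuple[int, ...] = (3, 5, 7, 9, 11)
    ndvi_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    model_forms: tuple[str, ...] = ("linear", "quadratic")
    cell_size_m: float = 20.0
    out_dir: str = "standcount_out"
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int | None) -> "RunConfig":
        if seed is None:
            return self
        scene = dataclasses.replace(self.scene, seed=seed)
        return dataclasses.replace(self, scene=scene, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = dataclasses.asdict(self.scene)
        return d

    def snapshot(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=list))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        scene_raw = raw.pop("scene", {}) or {}
        try:
            scene_fields = {f.name for f in dataclasses.fields(SceneParams)}
            unknown = set(scene_raw) - scene_fields
            if unknown:
                raise ConfigError(f"unknown scene field(s): {sorted(unknown)}")
            for tuple_field in ("extent_m", "density_moments", "conifer_crown",
                               "broadleaf_crown"):
                if tuple_field in scene_raw:
                    scene_raw[tuple_field] = tuple(scene_raw[tuple_field])
            scene = SceneParams(**scene_raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scene config: {exc}") from exc
        cfg_fields = {f.name for f in dataclasses.fields(cls)} - {"scene"}
        unknown = set(raw) - cfg_fields
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        for tuple_field in ("bands", "window_sizes", "ndvi_thresholds", "model_forms"):
            if tuple_field in raw:
                raw[tuple_field] = tuple(raw[tuple_field])
        return cls(scene=scene, **raw)


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)
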