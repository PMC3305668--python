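"""Run configuration: validation and YAML/JSON round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import CameraModel
from .guide import JigSpec
from .nail import NailSpec


class ConfigError(ValueError):
    """Invalid or missing configuration; the message names the field."""


@dataclass
class DetectionParams:
    min_area_px: float = 30.0
    min_solidity: float = 0.85
    smoothing_sigma: float = 1.0
    circular_contrast: float = 3.0

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class SolverParams:
    prepass_iterations: int = 8
    refine_top: int = 2
    virtual_mode: str = "conic"

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class GuidanceParams:
    skin_offset_mm: float = 30.0
    drill_diameter_mm: float = 3.2

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class RunConfig:
    """Validated parameter bundle for a pipeline run."""

    camera: CameraModel = field(default_factory=CameraModel)
    nail: NailSpec = field(default_factory=lambda: NailSpec.default("parallel"))
    jig: JigSpec = field(default_factory=JigSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    solver: SolverParams = field(default_factory=SolverParams)
    guidance: GuidanceParams = field(default_factory=GuidanceParams)
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("configuration root must be a mapping")
        kw = {}
        for key, loader in (("camera", CameraModel.from_dict),
                            ("nail", NailSpec.from_dict),
                            ("jig", JigSpec.from_dict)):
            if key not in d:
                raise ConfigError(f"missing required config block: '{key}'")
            try:
                kw[key] = loader(d[key])
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"invalid '{key}' block: {exc}") from exc
        for key, klass in (("detection", DetectionParams),
                           ("solver", SolverParams),
                           ("guidance", GuidanceParams)):
            block = d.get(key, {})
            if not isinstance(block, dict):
                raise ConfigError(f"invalid '{key}' block: must be a mapping")
            try:
                kw[key] = klass(**block)
            except TypeError as exc:
                raise ConfigError(f"invalid '{key}' block: {exc}") from exc
        kw["seed"] = int(d.get("seed", 0))
        kw["verbosity"] = int(d.get("verbosity", 1))
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "camera": self.camera.to_dict(),
            "nail": self.nail.to_dict(),
            "jig": self.jig.to_dict(),
            "detection": self.detection.to_dict(),
            "solver": self.solver.to_dict(),
            "guidance": self.guidance.to_dict(),
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def save(self, path) -> str:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return str(path)
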