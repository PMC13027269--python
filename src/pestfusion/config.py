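"""YAML run configuration: nested blocks, strict keys, lossless round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocess import PreprocessConfig
from .synth import SynthConfig
from .train import TrainConfig


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "full"
    scale_factor: float = 1.0
    width_factor: float = 1.0
    attention_ratio: int = 4
    relational_unit: bool = True
    seed: int = 0


@dataclass(frozen=True)
class EvalConfig:
    folds: int = 5
    ratios: tuple = (0.70, 0.15, 0.15)


@dataclass
class RunConfig:
    """Top-level configuration tying the pipeline stages together."""

    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        out = {"seed": self.seed, "out_dir": self.out_dir,
               "log_level": self.log_level}
        for block in ("synth", "preprocess", "model", "train", "eval"):
            out[block] = convert(dataclasses.asdict(getattr(self, block)))
        return out

    def to_yaml(self, path: str | Path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        blocks = {"synth": SynthConfig, "preprocess": PreprocessConfig,
                  "model": ModelConfig, "train": TrainConfig, "eval": EvalConfig}
        kwargs = {}
        for name, klass in blocks.items():
            block = dict(data.pop(name, {}) or {})
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - valid
            if unknown:
                raise ValueError(
                    f"unknown key(s) in '{name}' block: {sorted(unknown)}")
            for key, val in block.items():
                if isinstance(val, list):
                    if name == "synth" and key == "env_class_shift":
                        block[key] = np.asarray(val, dtype=float)
                    else:
                        block[key] = tuple(tuple(v) if isinstance(v, list) else v
                                           for v in val)
            kwargs[name] = klass(**block)
        top_valid = {"seed", "out_dir", "log_level"}
        unknown = set(data) - top_valid
        if unknown:
            raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as err:
            mark = getattr(err, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"malformed YAML in {path}{line}: {err}") from err
        return cls.from_dict(data or {})
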