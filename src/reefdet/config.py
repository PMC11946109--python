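"""Run configuration: one YAML document wiring model preset, loss, training
hyperparameters and dataset paths, plus the reproducibility manifest written
beside every run's outputs."""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .architecture import ModelConfig, get_preset
from .losses import LossConfig, WIoUState
from .training import TrainConfig

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """Resolved configuration of one training run.

    Precedence: explicit CLI flags > values in the config file > preset
    defaults.  ``model``, ``loss`` and ``train`` are keyword overrides applied
    on top of the named preset / dataclass defaults.
    """

    dataset: str = ""
    preset: str = "micro"
    model: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    seed: int = 0
    device: str = "cpu"
    out_dir: str = "runs/exp"

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    # -- builders ------------------------------------------------------------
    def model_config(self, num_classes: int) -> ModelConfig:
        return get_preset(self.preset, num_classes=num_classes, **self.model)

    def loss_config(self) -> LossConfig:
        kwargs = dict(self.loss)
        wiou_kwargs = kwargs.pop("wiou", {})
        return LossConfig(wiou=WIoUState(**wiou_kwargs), **kwargs)

    def train_config(self) -> TrainConfig:
        kwargs = dict(self.train)
        kwargs.setdefault("seed", self.seed)
        return TrainConfig(**kwargs)


def write_manifest(out_dir, run_config: RunConfig, extra: dict | None = None) -> Path:
    """Record everything needed to re-execute a run bit-compatibly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": asdict(run_config),
        "seed": run_config.seed,
        "versions": {
            "reefdet": __version__,
            "numpy": np.__version__,
            "python": sys.version.split()[0],
            "platform": platform.platform(),
        },
    }
    if extra:
        payload.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
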