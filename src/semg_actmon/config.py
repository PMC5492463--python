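"""Run configuration: YAML round-trip, defaults, validation, provenance hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifiers import METHODS
from .features import FEATURE_IDS
from .synth import GeneratorConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run.

    Defaults are the study conditions: 1024 Hz / 1.5 s epochs, WAMP threshold
    0.05, 21 histogram bins on [−5, 5], AR order 4, db8 wavelet at level 5,
    kernel-width grid 0.5–5 step 0.1, five-fold CV.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: list[str] = field(default_factory=lambda: list(FEATURE_IDS))
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    cv_seed: int = 0
    per_subject: bool = True
    w_sweep: list[float] = field(
        default_factory=lambda: [round(float(w), 10) for w in np.arange(0.0, 0.5001, 0.05)]
    )
    out_dir: str = "results"
    verbosity: int = 1

    def validate(self) -> None:
        self.generator.validate()
        bad = [f for f in self.features if f not in FEATURE_IDS]
        if bad:
            raise ValueError(f"unknown feature ids {bad}; valid: {', '.join(FEATURE_IDS)}")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; valid: {', '.join(METHODS)}")
        if any(w < 0 or w > 0.5 for w in self.w_sweep):
            raise ValueError("w values must lie in [0, 0.5]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; missing keys take their defaults.

    An empty file yields the all-defaults configuration.
    """
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical config JSON, for output provenance."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
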