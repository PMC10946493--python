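"""Experiment configuration: YAML/JSON round-trip with strict key checking.

Every experiment run is described by an :class:`ExperimentConfig` with a
mandatory seed; result files are written next to a JSON sidecar carrying the
config echo, its hash and the package version, so any CSV can be traced back
to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "load_config", "save_config", "write_sidecar"]

_KNOWN_EXPERIMENTS = ("store-recall", "capacity", "fov", "gain", "info", "demo-all")


@dataclass
class ExperimentConfig:
    """Umbrella config: experiment id, seed, output dir, and a parameter
    block specific to the experiment family."""

    experiment: str
    seed: int
    out_dir: str = "."
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in _KNOWN_EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"expected one of {_KNOWN_EXPERIMENTS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_FIELDS = {"experiment", "seed", "out_dir", "params"}


def load_config(path) -> ExperimentConfig:
    """Load a YAML or JSON experiment config; unknown top-level keys are
    rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ValueError("seed is mandatory")
    return ExperimentConfig(**data)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_sidecar(cfg: ExperimentConfig, result_path) -> None:
    """Write the JSON sidecar (config echo, hash, seed) next to a result file."""
    from . import __version__
    side = Path(str(result_path) + ".json")
    side.write_text(json.dumps({
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "svcsim_version": __version__,
    }, indent=2, sort_keys=True))
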