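"""Flat key-value configuration files and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from ..detector_core import DetectorConfig, InputError

__all__ = ["load_config", "dump_config", "RunManifest"]


def load_config(path: Optional[str] = None, **overrides) -> DetectorConfig:
    """Build a :class:`DetectorConfig` from a flat YAML file plus overrides.

    Missing keys fall back to the library defaults so the file only needs to
    list what it changes.
    """
    mapping: Dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"{path}: config must be a flat key-value mapping")
        mapping.update(loaded)
    mapping.update({k: v for k, v in overrides.items() if v is not None})
    return DetectorConfig.from_mapping(mapping)


def dump_config(cfg: DetectorConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    config: Dict[str, object]
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    version: str = ""
    timings_s: Dict[str, float] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


class StageTimer:
    """Tiny helper collecting per-stage wall-clock timings for manifests."""

    def __init__(self) -> None:
        self.timings: Dict[str, float] = {}
        self._t0: Optional[float] = None
        self._stage: Optional[str] = None

    def start(self, stage: str) -> None:
        self._stage = stage
        self._t0 = time.perf_counter()

    def stop(self) -> None:
        if self._stage is not None and self._t0 is not None:
            self.timings[self._stage] = round(time.perf_counter() - self._t0, 6)
        self._stage = None
        self._t0 = None
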