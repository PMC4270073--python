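"""Run configuration, validation, and deterministic per-stage seeding.

Config files are YAML, either nested blocks or flat dotted keys
(``oscillator.period: 24``). Unknown keys are rejected. Defaults are the
strong-selection regime: 6% tails, a 10:14-hr schedule, and a 0.95 causal
threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import numpy as np
import yaml

from .errors import ConfigError
from .facs import ScheduleSpec
from .params import OscillatorParams

__all__ = ["RunConfig", "SegregantConfig", "TrajectoryConfig", "load_config", "child_seed"]

# fixed stage order: the global seed expands to independent child seeds by
# SeedSequence(seed, spawn_key=(stage_index,)), so any stage can be rerun
# on its own and reproduce exactly
STAGES = ("simulate", "synchronize", "metrics", "segregant", "trajectory", "fixtures")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child of the global seed (< 2**31)."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; known: {STAGES}")
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SegregantConfig:
    n_spores: int = 10_000
    depth: float = 100.0
    threshold: float = 0.95
    n_causal: int = 8
    n_neutral: int = 20

    def __post_init__(self):
        if self.n_spores < 1 or self.depth < 1:
            raise ConfigError("n_spores and depth must be >= 1")
        if not 0 < self.threshold <= 1:
            raise ConfigError("threshold must be in (0, 1]")
        if self.n_causal < 0 or self.n_neutral < 0:
            raise ConfigError("locus counts must be >= 0")


@dataclass
class TrajectoryConfig:
    days: int = 30
    pop_size: int = 100_000
    generations_per_day: int = 6
    selection_strength: float = 0.05

    def __post_init__(self):
        if self.days < 1 or self.pop_size < 2 or self.generations_per_day < 1:
            raise ConfigError("trajectory sizes must be positive")
        if self.selection_strength < 0:
            raise ConfigError("selection_strength must be >= 0")


@dataclass
class RunConfig:
    oscillator: OscillatorParams = field(default_factory=OscillatorParams)
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    segregant: SegregantConfig = field(default_factory=SegregantConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    gate_fraction: float = 0.06
    n_events: int = 10_000
    keep_cells: int = 1_000
    n_cells: int = 2_000
    dt: float = 0.25
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self):
        if not 0 < self.gate_fraction <= 1:
            raise ConfigError(
                f"gate_fraction must be in (0, 1], got {self.gate_fraction}"
            )
        if self.n_events < 2 or self.keep_cells < 1 or self.n_cells < 1:
            raise ConfigError("n_events, keep_cells, n_cells must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")

    def config_hash(self) -> str:
        """Stable hash of the config contents (for run logs)."""
        payload = json.dumps(_as_plain(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_as_plain(x) for x in obj]
    return obj


def _flatten(d: Dict[str, Any], prefix: str = "") -> Dict[str, Any]:
    flat: Dict[str, Any] = {}
    for key, value in d.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, full + "."))
        else:
            flat[full] = value
    return flat


_BLOCKS = {
    "oscillator": OscillatorParams,
    "segregant": SegregantConfig,
    "trajectory": TrajectoryConfig,
}
_TOP_FIELDS = {
    "gate_fraction",
    "n_events",
    "keep_cells",
    "n_cells",
    "dt",
    "seed",
    "out_dir",
    "schedule",
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")

    # schedule is a list block, handle before flattening
    schedule_raw = raw.pop("schedule", None)
    flat = _flatten(raw)
    block_kwargs: Dict[str, Dict[str, Any]] = {name: {} for name in _BLOCKS}
    top_kwargs: Dict[str, Any] = {}
    for key, value in flat.items():
        if "." in key:
            block, _, fname = key.partition(".")
            if block not in _BLOCKS:
                raise ConfigError(f"unknown config block {block!r} (key {key!r})")
            valid = {f.name for f in dataclasses.fields(_BLOCKS[block])}
            if fname not in valid:
                raise ConfigError(f"unknown key {key!r}")
            block_kwargs[block][fname] = value
        elif key in _TOP_FIELDS:
            top_kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")

    try:
        blocks = {name: cls(**block_kwargs[name]) for name, cls in _BLOCKS.items()}
        schedule = (
            ScheduleSpec(tuple((float(i), str(a)) for i, a in schedule_raw))
            if schedule_raw is not None
            else ScheduleSpec()
        )
        return RunConfig(schedule=schedule, **blocks, **top_kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
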