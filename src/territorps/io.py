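"""Config files and lattice snapshot persistence.

Two snapshot codecs: an ``.npz`` container (grid + generation + the JSON of
the config that produced it) for real runs, and a plain-text CSV codec
(one lattice row per line, integer codes 0-6) for tiny fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .model_core import ConfigError, LatticeState, SimulationConfig, validate_config

__all__ = [
    "load_config",
    "dump_config",
    "save_snapshot",
    "load_snapshot",
    "grid_to_csv",
    "grid_from_csv",
]

_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Read a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return validate_config(SimulationConfig(**data))


def dump_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def save_snapshot(
    state: LatticeState,
    path: Union[str, Path],
    config: Optional[SimulationConfig] = None,
) -> None:
    """Write a snapshot as a compressed array container with a config sidecar."""
    meta = json.dumps(dataclasses.asdict(config)) if config is not None else ""
    np.savez_compressed(
        path,
        grid=state.grid,
        generation=np.int64(state.generation),
        config_json=np.array(meta),
    )


def load_snapshot(path: Union[str, Path]):
    """Read a snapshot; returns ``(LatticeState, SimulationConfig or None)``."""
    with np.load(path, allow_pickle=False) as data:
        state = LatticeState(data["grid"], generation=int(data["generation"]))
        meta = str(data["config_json"])
    config = SimulationConfig(**json.loads(meta)) if meta else None
    return state, config


def grid_to_csv(state: LatticeState, path: Union[str, Path]) -> None:
    """Plain-text codec: ``# generation=g`` header then one CSV line per row."""
    with open(path, "w") as fh:
        fh.write(f"# generation={state.generation}\n")
        for row in state.grid:
            fh.write(",".join(str(int(x)) for x in row) + "\n")


def grid_from_csv(path: Union[str, Path]) -> LatticeState:
    generation = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "generation=" in line:
                    generation = int(line.split("generation=")[1])
                continue
            rows.append([int(x) for x in line.split(",")])
    return LatticeState(np.array(rows, dtype=np.int8), generation=generation)
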