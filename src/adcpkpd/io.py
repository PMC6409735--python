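"""Configuration parsing, observation-table I/O, and run manifests.

One long-format CSV schema serves simulation output, NCA input, fixture
generation and fitting: columns ``time_d, matrix, analyte, model,
dose_mg_kg, subject, value, units`` (simulation output omits the subject
columns it has no use for).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .units import UnitError

OBS_COLUMNS = ("time_d", "matrix", "analyte", "model", "dose_mg_kg",
               "subject", "value", "units")

_COMMANDS = ("simulate", "nca", "fit", "generate", "recover")


@dataclass
class RunConfig:
    """Validated top-level run description."""

    command: str
    params_path: str | None = None
    data_path: str | None = None
    out_path: str | None = None
    model: str = "n87"
    dose_mg_per_kg: float = 10.0
    mode: str = "pkpd"
    t_end: float = 7.0
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    verbosity: int = 1


def parse_config(path) -> RunConfig:
    """Read a YAML/JSON run config, rejecting unknown keys by name."""
    path = Path(path)
    if not path.exists():
        raise UnitError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise UnitError("config must be a mapping")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(doc) - known
    if unknown:
        raise UnitError(f"unknown config key(s): {sorted(unknown)}")
    if "command" not in doc:
        raise UnitError("config must name a command")
    if doc["command"] not in _COMMANDS:
        raise UnitError(f"unknown command '{doc['command']}'; "
                        f"choose from {_COMMANDS}")
    return RunConfig(**doc)


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_d", "matrix", "analyte", "value")
               if c not in df.columns]
    if missing:
        raise UnitError(f"observation table missing column(s): {missing}")
    if (df["value"] < 0).any():
        raise UnitError("observation values must be >= 0")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_manifest(path, *, command: str, seed: int | None,
                   parameters: dict | None = None, **extra) -> None:
    """Emit a JSON manifest sufficient to re-run the command byte-identically."""
    doc = {
        "command": command,
        "seed": seed,
        "parameters": parameters or {},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
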