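"""File formats, configuration and reproducibility plumbing.

Conventions: tidy (long) CSV tables; every angle column carries a
``_deg`` suffix, lengths ``_cm`` and times ``_s``.  A run directory
always contains a manifest (config snapshot, master and per-repetition
seeds, software version, input digests, timestamp) written before any
other output, sufficient to reproduce the run bitwise.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .retina import wrap_angle
from .simulator import SimulationConfig, repetition_seed

__all__ = [
    "RunManifest",
    "read_trajectories",
    "write_trajectories",
    "read_config",
    "write_config",
    "write_run",
]

TRAJ_COLUMNS = ["time_s", "animal_id", "x_cm", "y_cm", "heading_deg"]
ID_ALIASES = ("animal_id", "fish_id", "agent_id")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bitwise."""

    config: dict
    master_seed: int
    n_repetitions: int = 1
    software_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    timestamp: str = ""
    repetition_seeds: list = field(default_factory=list)

    def __post_init__(self):
        if not self.repetition_seeds:
            self.repetition_seeds = [
                repetition_seed(self.master_seed, r) for r in range(self.n_repetitions)
            ]
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "master_seed": self.master_seed,
                "n_repetitions": self.n_repetitions,
                "repetition_seeds": self.repetition_seeds,
                "software_version": self.software_version,
                "input_digests": self.input_digests,
                "timestamp": self.timestamp,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            config=d["config"],
            master_seed=d["master_seed"],
            n_repetitions=d.get("n_repetitions", 1),
            software_version=d.get("software_version", ""),
            input_digests=d.get("input_digests", {}),
            timestamp=d.get("timestamp", ""),
            repetition_seeds=d.get("repetition_seeds", []),
        )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_trajectories(path: str | Path, arena_diameter_cm: float | None = None) -> pd.DataFrame:
    """Read and validate a tidy trajectory CSV.

    Requires columns ``time_s, animal_id (or fish_id/agent_id), x_cm,
    y_cm, heading_deg``.  Rows are sorted (order-insensitive read),
    headings wrapped to (-180, 180]; per-animal time must be strictly
    increasing and uniformly spaced, positions finite (and inside the
    arena when its diameter is given).  Errors cite row numbers.
    """
    df = pd.read_csv(path)
    id_col = next((c for c in ID_ALIASES if c in df.columns), None)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns and c != "animal_id"]
    if id_col is None:
        missing.append("animal_id")
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.rename(columns={id_col: "animal_id"})

    bad = df.index[~np.isfinite(df[["x_cm", "y_cm"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-finite positions at rows {list(bad[:5])}")
    df = df.sort_values(["animal_id", "time_s"], kind="mergesort").reset_index(drop=True)
    for aid, sub in df.groupby("animal_id"):
        t = sub["time_s"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = sub.index[1:][dt <= 0][0]
            raise ValueError(f"{path}: non-monotone time for animal {aid} at row {row}")
        if dt.size and np.any(np.abs(dt - dt[0]) > 1e-6):
            row = sub.index[1:][np.abs(dt - dt[0]) > 1e-6][0]
            raise ValueError(f"{path}: irregular frame spacing for animal {aid} at row {row}")
    if arena_diameter_cm is not None:
        r = np.hypot(df["x_cm"], df["y_cm"])
        bad = df.index[r > arena_diameter_cm / 2 + 1e-6]
        if len(bad):
            raise ValueError(f"{path}: positions outside arena at rows {list(bad[:5])}")
    df["heading_deg"] = wrap_angle(df["heading_deg"].to_numpy())
    return df


def write_trajectories(df: pd.DataFrame, path: str | Path):
    cols = [c for c in TRAJ_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in TRAJ_COLUMNS
    ]
    df[cols].to_csv(path, index=False, float_format="%.8g")


def read_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML mapping of field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    return SimulationConfig(**raw)


def write_config(config: SimulationConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_run(
    outputs: dict,
    manifest: RunManifest,
    out_dir: str | Path,
) -> dict:
    """Write a run directory: manifest first, then tables.

    ``outputs`` maps names to DataFrames (written as ``<name>.csv``).
    Returns the paths written.  Raises before any computation output is
    written if the directory cannot be created.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    mpath = out / "manifest.json"
    mpath.write_text(manifest.to_json())
    paths["manifest"] = mpath
    for name, df in outputs.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        paths[name] = p
    return paths
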