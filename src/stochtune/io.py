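"""Trajectory/table output and run manifests.

All tabular output is TSV with '.' decimals and shortest-round-trip float
formatting (Python's default ``str``), so files re-read bit-identically.
Every CLI run writes exactly one JSON manifest recording the command,
config echo, seeds, UTC timestamp, package version and output inventory.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["write_trajectory", "read_trajectory", "write_table", "RunManifest", "write_manifest"]


def _thin_indices(n_rows: int, thin: int) -> np.ndarray:
    """Every thin-th row plus the first and last."""
    if thin < 1:
        raise ValueError("thin must be >= 1")
    idx = np.arange(0, n_rows, thin)
    if idx[-1] != n_rows - 1:
        idx = np.append(idx, n_rows - 1)
    return idx


def write_trajectory(trajectory, path: str | Path, thin: int = 1) -> Path:
    """Write a trajectory's per-step series as TSV.

    Works for both simulator trajectory types: always writes ``step`` and
    ``fitness`` columns; abstract trajectories add any fully tracked gene
    series, physiological trajectories are written at their recorded
    (already thinned) steps with x/p/mu/nu columns per gene.
    """
    path = Path(path)
    if hasattr(trajectory, "gene_series"):  # abstract model
        n = len(trajectory.fitness)
        cols = {"step": np.arange(n), "fitness": trajectory.fitness}
        for g, series in trajectory.gene_series.items():
            cols[f"E_gene{g}"] = series
        df = pd.DataFrame(cols).iloc[_thin_indices(n, thin)]
    else:  # physiological model
        steps = trajectory.recorded_steps
        cols = {"step": steps, "fitness": trajectory.fitness[steps]}
        for name in ("x", "p", "mu", "nu"):
            arr = getattr(trajectory, name)
            for g in range(arr.shape[1]):
                cols[f"{name}_gene{g}"] = arr[:, g]
        df = pd.DataFrame(cols).iloc[_thin_indices(len(steps), thin)]
    # repr gives shortest-round-trip formatting so files re-read bit-exactly
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory TSV back with bit-exact float parsing."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: list[int]
    outputs: list[str]
    version: str = __version__
    timestamp_utc: str = ""
    argv: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.timestamp_utc:
            self.timestamp_utc = datetime.now(timezone.utc).isoformat()
        if not self.argv:
            self.argv = list(sys.argv)


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(manifest), indent=2, default=str) + "\n")
    return path
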