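"""Delimited-text readers/writers, config parsing and run provenance.

Table formats (CSV, comma-delimited, 17 significant digits):

* ensemble/PDE profile table: columns (t, x, N, E), one row per recording
  time x column, sorted by (t, x);
* snapshot table: columns (t, i, j, species, count) with species in
  {TC, EC}, one row per occupied site.

Config files are TOML with keys mirroring :class:`CAConfig` field names.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .averaging import EnsembleSummary
from .config import CAConfig, ConfigError
from .continuum import PDESolution

__all__ = [
    "parse_config", "write_config", "read_table", "write_table",
    "write_snapshots", "RunManifest",
]

_FLOAT_FMT = "%.17g"
_CA_KEYS = {"R", "P_m", "k", "tau", "P_p", "a_n", "a_e", "mode", "K_IC",
            "K_max", "seed"}


def parse_config(path) -> CAConfig:
    """Load and validate a CAConfig from a TOML file.

    Unknown keys and invariant violations raise descriptive errors; the
    ``h`` key, if present, must be consistent with 1/R.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    h = raw.pop("h", None)
    unknown = set(raw) - _CA_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = CAConfig(**raw)
    if h is not None and abs(h - cfg.h) > 1e-12:
        raise ConfigError(f"h={h} inconsistent with R={cfg.R} (R*h must be 1)")
    return cfg


def write_config(cfg: CAConfig, path) -> None:
    lines = []
    for k, v in cfg.to_dict().items():
        if isinstance(v, float):
            lines.append(f"{k} = {v!r}")
        else:
            lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(obj, path) -> None:
    """Write an EnsembleSummary or PDESolution as a (t, x, N, E) table."""
    rows = []
    for r, t in enumerate(obj.times):
        for i, x in enumerate(obj.x_grid):
            rows.append((t, x, obj.N[r, i], obj.E[r, i]))
    df = pd.DataFrame(rows, columns=["t", "x", "N", "E"])
    df.sort_values(["t", "x"], inplace=True, kind="stable")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_table(path, M: int = 0, kind: str = "ensemble"):
    """Read a (t, x, N, E) table back into an EnsembleSummary
    (kind="ensemble", with realization count M) or PDESolution
    (kind="pde").  The row count must be (number of times) x (number of
    columns)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "x", "N", "E"} - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    df = df.sort_values(["t", "x"], kind="stable")
    times = np.unique(df["t"].to_numpy())
    x = np.unique(df["x"].to_numpy())
    if df.shape[0] != times.size * x.size:
        raise ValueError(
            f"malformed table: {df.shape[0]} rows != {times.size} times x {x.size} columns")
    N = df["N"].to_numpy().reshape(times.size, x.size)
    E = df["E"].to_numpy().reshape(times.size, x.size)
    if kind == "pde":
        return PDESolution(x_grid=x, times=times, N=N, E=E)
    return EnsembleSummary(times=times, x_grid=x, N=N, E=E, M=M)


def write_snapshots(snapshots, record_K, tau: float, path) -> None:
    """Write per-realization occupancy snapshots as a (t, i, j, species,
    count) table, one row per occupied site (supports re-drawing the
    network panels)."""
    rows = []
    for (tc, ec), K in zip(snapshots, record_K):
        t = tau * K
        for i, j in zip(*np.nonzero(tc)):
            rows.append((t, int(i), int(j), "TC", 1))
        for i, j in zip(*np.nonzero(ec)):
            rows.append((t, int(i), int(j), "EC", int(ec[i, j])))
    df = pd.DataFrame(rows, columns=["t", "i", "j", "species", "count"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class RunManifest:
    """Provenance record of a pipeline run: config snapshot, seed block,
    code version, timestamps and a registry of output files with content
    hashes."""

    config: dict
    seeds: dict
    version: str = ""
    created: str = field(default_factory=lambda: datetime.datetime.now().isoformat())
    outputs: dict = field(default_factory=dict)

    def register(self, label: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[label] = {"path": str(path), "sha256": digest}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
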