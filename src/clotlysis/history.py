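"""Time-series container shared by all simulation tiers."""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError


@dataclass
class SimulationHistory:
    """Time-stamped simulation output.

    ``t`` is a strictly increasing time array (s).  ``columns`` maps a name
    to a 1-D array aligned with ``t`` (scalar diagnostics per step).
    ``snapshots`` optionally stores heavier field data: a list of
    ``(time, {name: ndarray})`` pairs taken on a coarser schedule.
    ``metadata`` records how the run was produced.
    """

    t: np.ndarray
    columns: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ConfigError("history times must be strictly increasing")
        for name, col in self.columns.items():
            col = np.asarray(col)
            if col.shape[0] != self.t.shape[0]:
                raise ConfigError(
                    f"column {name!r} has {col.shape[0]} rows, expected {self.t.shape[0]}"
                )
            self.columns[name] = col

    def __len__(self):
        return int(self.t.size)

    def column(self, name: str) -> np.ndarray:
        return np.asarray(self.columns[name])

    def snapshot_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.snapshots])

    def to_csv(self, path) -> Path:
        """Write the scalar time series as CSV (t plus all columns)."""
        path = Path(path)
        names = list(self.columns)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t"] + names)
            for i, ti in enumerate(self.t):
                w.writerow([repr(float(ti))] + [repr(float(self.columns[n][i])) for n in names])
        return path

    def config_hash(self) -> str:
        """Stable hash of the metadata block (provenance tag for outputs)."""
        blob = json.dumps(self.metadata, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
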