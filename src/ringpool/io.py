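"""Event-list and report I/O.

Interchange formats are deliberately plain: event lists are
single-column CSV files (``mass_kDa``) with a JSON metadata sidecar;
reports are JSON carrying the tool version, seed and a config hash so
every artifact is traceable to the run that made it.  A generic HDF5
container (one dataset of masses) mirrors instrument exports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventList",
    "read_events",
    "write_events",
    "read_events_hdf5",
    "write_report",
    "config_hash",
]


@dataclass(frozen=True)
class EventList:
    """Single-molecule landing events: one calibrated mass per event."""

    masses: np.ndarray  # kDa
    concentration_nM: float | None = None
    duration_s: float = 60.0
    replicate: int = 0
    fov: str = "regular"
    n_discarded: int = 0  # events below the detection limit, dropped
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        if masses.size and (not np.all(np.isfinite(masses)) or np.any(masses <= 0)):
            raise ValueError("event masses must be finite and > 0")
        if self.duration_s <= 0:
            raise ValueError("acquisition duration must be > 0")

    def __len__(self) -> int:
        return int(self.masses.size)

    def metadata(self) -> dict:
        return {
            "concentration_nM": self.concentration_nM,
            "duration_s": self.duration_s,
            "replicate": self.replicate,
            "fov": self.fov,
            "n_discarded": self.n_discarded,
            **self.meta,
        }


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_events(events: EventList, path) -> Path:
    """Write an event list as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    # %.17g guarantees an exact float round trip through the text form
    pd.DataFrame({"mass_kDa": events.masses}).to_csv(
        path, index=False, float_format="%.17g"
    )
    with open(_sidecar(path), "w") as fh:
        json.dump(events.metadata(), fh, indent=2)
    return path


def read_events(path) -> EventList:
    """Read an event-list CSV (column ``mass_kDa``) and its sidecar."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    if "mass_kDa" not in raw.columns:
        raise ValueError(f"{path}: expected a 'mass_kDa' column")
    vals = pd.to_numeric(raw["mass_kDa"], errors="coerce")
    bad = vals.index[vals.isna() & raw["mass_kDa"].notna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: non-numeric mass on line(s) {lines}")
    # python's float() is correctly rounded; pandas' fast parser is not,
    # which would break exact write->read round trips
    masses = np.array(
        [float(s) for s in raw["mass_kDa"].dropna()], dtype=float
    )
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    known = {
        k: meta.pop(k)
        for k in ("concentration_nM", "duration_s", "replicate", "fov", "n_discarded")
        if k in meta
    }
    return EventList(masses=masses, meta=meta, **known)


def read_events_hdf5(path, dataset: str = "masses", **meta) -> EventList:
    """Ingest a generic HDF5 events container (one dataset of masses, kDa)."""
    import h5py

    with h5py.File(path, "r") as fh:
        if dataset not in fh:
            raise ValueError(f"{path}: no dataset named '{dataset}'")
        masses = np.asarray(fh[dataset][...], dtype=float).ravel()
    return EventList(masses=masses, **meta)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(payload: dict, path, config: dict | None = None, seed=None) -> Path:
    """Write a JSON report stamped with version, config hash and seed."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    doc = {
        "tool": "ringpool",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        **payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return path
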