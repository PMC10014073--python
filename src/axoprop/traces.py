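"""Multi-site time-series container and its plain-text file format.

A :class:`TraceSet` holds channels sampled on one uniform time grid, each
channel carrying site metadata (axial distance from the soma edge, region,
recorded quantity).  On disk a trace set is a CSV whose first column is
``time_ms`` plus one column per channel, with a JSON sidecar
(``<name>.meta.json``) holding channel metadata and any generator
ground truth.  Files without a sidecar are readable; their distances default
to NaN with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("axoprop")

__all__ = ["Channel", "TraceSet", "read_traceset", "write_traceset"]

QUANTITIES = ("V", "I_membrane", "I_clamp", "Na_i", "Vcmd")


@dataclass
class Channel:
    """One recorded signal: samples plus site metadata."""

    name: str
    samples: np.ndarray
    quantity: str = "V"  # V | I_membrane | I_clamp | Na_i | Vcmd
    distance: float = float("nan")  # um from the soma edge (NaN if unknown)
    region: str | None = None
    units: str | None = None
    sweep: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.units is None:
            self.units = {
                "V": "mV",
                "Vcmd": "mV",
                "I_membrane": "nA",
                "I_clamp": "nA",
                "Na_i": "mM",
            }.get(self.quantity, "")


@dataclass
class TraceSet:
    """Channels on a shared uniform time grid (ms)."""

    time: np.ndarray
    channels: list[Channel]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for ch in self.channels:
            if len(ch.samples) != len(self.time):
                raise ValueError(
                    f"channel {ch.name!r}: {len(ch.samples)} samples on a "
                    f"{len(self.time)}-point time grid"
                )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else float("nan")

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, name: str) -> Channel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(name)

    def select(self, quantity: str | None = None, region: str | None = None) -> list[Channel]:
        out = []
        for ch in self.channels:
            if quantity is not None and ch.quantity != quantity:
                continue
            if region is not None and ch.region != region:
                continue
            out.append(ch)
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.time}
        for ch in self.channels:
            data[ch.name] = ch.samples
        return pd.DataFrame(data)


def write_traceset(ts: TraceSet, path: str | Path, float_format: str = "%.9g") -> None:
    """Write CSV (time_ms first column) plus a JSON metadata sidecar."""
    path = Path(path)
    ts.to_frame().to_csv(path, index=False, float_format=float_format)
    sidecar = {
        "channels": [
            {
                "name": ch.name,
                "quantity": ch.quantity,
                "distance_um": None if np.isnan(ch.distance) else ch.distance,
                "region": ch.region,
                "units": ch.units,
                "sweep": ch.sweep,
            }
            for ch in ts.channels
        ],
        "meta": _jsonify(ts.meta),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_traceset(path: str | Path) -> TraceSet:
    """Read a trace-set CSV; use the sidecar for metadata when present."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0] != "time_ms":
        raise ValueError(
            f"malformed trace file {path}: first column must be 'time_ms'"
        )
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    chan_meta: dict[str, dict] = {}
    meta: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        chan_meta = {c["name"]: c for c in sidecar.get("channels", [])}
        meta = sidecar.get("meta", {})
    else:
        logger.warning(
            "no metadata sidecar for %s; channel distances default to NaN", path
        )
    channels = []
    for col in frame.columns[1:]:
        cm = chan_meta.get(col, {})
        dist = cm.get("distance_um")
        channels.append(
            Channel(
                name=col,
                samples=frame[col].to_numpy(),
                quantity=cm.get("quantity", "V"),
                distance=float("nan") if dist is None else float(dist),
                region=cm.get("region"),
                units=cm.get("units"),
                sweep=cm.get("sweep"),
            )
        )
    return TraceSet(time=frame["time_ms"].to_numpy(), channels=channels, meta=meta)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
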