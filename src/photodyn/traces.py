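"""Stimulus and response time series, with CSV + sidecar-JSON round-trip I/O.

Trace files are plain CSV with header ``time_ms,value``; a sidecar JSON
(``<name>.meta.json``) records the unit and provenance so that a written
trace can be reloaded bit-exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .grid import TimeGrid

PER_MS = "photons/um^2/ms"
PER_S = "photons/um^2/s"


def convert_intensity(values: np.ndarray, from_unit: str, to_unit: str) -> np.ndarray:
    """Exact factor-1000 rescaling between per-second and per-ms intensity."""
    if from_unit == to_unit:
        return values
    pair = (from_unit, to_unit)
    if pair == (PER_S, PER_MS):
        return values / 1000.0
    if pair == (PER_MS, PER_S):
        return values * 1000.0
    raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")


@dataclass
class StimulusTrace:
    """Nonnegative light intensity per sample, photons/um^2/ms."""

    grid: TimeGrid
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n,):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid n={self.grid.n}"
            )
        if not self.metadata.get("allow_negative", False) and np.any(self.intensity < 0):
            raise ValueError("stimulus intensity must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def integral(self) -> float:
        """Time integral of the intensity, photons/um^2."""
        return float(np.trapezoid(self.intensity, dx=self.grid.dt))

    def with_intensity(self, intensity: np.ndarray, **meta) -> "StimulusTrace":
        md = dict(self.metadata)
        md.update(meta)
        return StimulusTrace(self.grid, intensity, md)


@dataclass
class ResponseTrace:
    """Photoreceptor response R(t) in mV relative to the dark resting level.

    With the hyperpolarizing sign convention, R <= 0 under illumination.
    Optional companion signals hold the filtered drives y(t) and z(t).
    """

    grid: TimeGrid
    response: np.ndarray
    y: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.grid.n,):
            raise ValueError("response length does not match grid")

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def peak(self) -> tuple[float, float]:
        """(peak hyperpolarization magnitude in mV, time of the peak in ms)."""
        i = int(np.argmin(self.response))
        return float(-self.response[i]), float(self.times[i])


# --------------------------------------------------------------------------
# CSV I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_trace(trace, path, unit: Optional[str] = None) -> None:
    """Write a trace as ``time_ms,value`` CSV plus a metadata sidecar.

    Values are written with full float repr so that read-back is bit-exact.
    """
    path = Path(path)
    if isinstance(trace, StimulusTrace):
        values, kind = trace.intensity, "stimulus"
        unit = unit or PER_MS
    elif isinstance(trace, ResponseTrace):
        values, kind = trace.response, "response"
        unit = unit or "mV"
    else:
        raise TypeError(f"cannot write object of type {type(trace)}")
    with open(path, "w") as fh:
        fh.write("time_ms,value\n")
        for t, v in zip(trace.grid.times, values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    meta = {
        "kind": kind,
        "unit": unit,
        "grid": {"t0": trace.grid.t0, "dt": trace.grid.dt, "n": trace.grid.n},
        "metadata": _jsonable(trace.metadata),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_trace(path, assume_unit: Optional[str] = None):
    """Read a trace CSV written by :func:`write_trace`.

    Returns a :class:`StimulusTrace` or :class:`ResponseTrace` depending on
    the sidecar ``kind``. Files without a sidecar are rejected unless
    ``assume_unit`` is given. Malformed rows raise with the line number.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    elif assume_unit is not None:
        meta = {"kind": "stimulus" if assume_unit != "mV" else "response",
                "unit": assume_unit, "grid": None, "metadata": {}}
    else:
        raise ValueError(
            f"{path}: no unit sidecar {side.name}; pass assume_unit to override"
        )

    times, values = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_ms,value":
            raise ValueError(f"{path}:1: expected header 'time_ms,value', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None

    times = np.asarray(times)
    values = np.asarray(values)
    if meta.get("grid"):
        g = meta["grid"]
        grid = TimeGrid(t0=g["t0"], dt=g["dt"], n=g["n"])
    else:
        if len(times) < 2:
            raise ValueError(f"{path}: cannot infer grid from fewer than 2 samples")
        dt = float(times[1] - times[0])
        grid = TimeGrid(t0=float(times[0]), dt=dt, n=len(times))

    unit = meta["unit"]
    md = dict(meta.get("metadata") or {})
    if meta["kind"] == "stimulus":
        vals = convert_intensity(values, unit if unit in (PER_S, PER_MS) else PER_MS, PER_MS)
        if unit == PER_S:
            md["declared_unit"] = PER_S
        return StimulusTrace(grid, vals, md)
    return ResponseTrace(grid, values, metadata=md)


def trace_frame(trace) -> pd.DataFrame:
    """Trace as a two-column DataFrame (convenience for analysis scripts)."""
    values = trace.intensity if isinstance(trace, StimulusTrace) else trace.response
    return pd.DataFrame({"time_ms": trace.grid.times, "value": values})
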