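"""Uniform time grids shared by stimulus and response traces."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """A uniformly sampled time axis.

    Parameters
    ----------
    t0 : float
        Start time in ms.
    dt : float
        Sample step in ms, > 0.
    n : int
        Number of samples, >= 1.
    """

    t0: float
    dt: float
    n: int

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Span from first to last sample, ms."""
        return self.dt * (self.n - 1)

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def index_of(self, t: float) -> int:
        """Nearest sample index for time t (must lie within the grid)."""
        i = int(round((t - self.t0) / self.dt))
        if i < 0 or i >= self.n:
            raise ValueError(f"time {t} ms outside grid [{self.t0}, {self.t_end}]")
        return i

    @classmethod
    def from_duration(cls, duration: float, dt: float, t0: float = 0.0) -> "TimeGrid":
        """Grid covering [t0, t0 + duration] inclusive of both endpoints."""
        return cls(t0=t0, dt=dt, n=int(round(duration / dt)) + 1)

    def compatible_with(self, other: "TimeGrid", rtol: float = 1e-9) -> bool:
        return abs(self.dt - other.dt) <= rtol * self.dt


def require_same_grid(a: TimeGrid, b: TimeGrid) -> None:
    if a != b:
        raise ValueError(f"grids differ: {a} vs {b}")
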