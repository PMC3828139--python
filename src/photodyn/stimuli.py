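"""Stimulus generators: flashes, steps, sinusoids, Gaussian flicker, and a
synthetic naturalistic-intensity surrogate.

All generators are deterministic given (spec, seed, grid), return
:class:`~photodyn.traces.StimulusTrace` objects carrying full provenance
metadata, and produce nonnegative intensities (subject to the declared
clip policy for Gaussian flicker, whose draws can cross zero).

Flashes are specified by their *integrated* photon count (photons/um^2)
and rendered as boxcars of a given duration, so that captions quoting
either integrated intensities or rate-times-duration map onto the same
primitive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .grid import TimeGrid
from .traces import StimulusTrace


# --------------------------------------------------------------------------
# deterministic protocols


@dataclass(frozen=True)
class PulseEvent:
    """One flash or step.

    ``amplitude`` is integrated photons/um^2 for flashes (spread uniformly
    over ``duration``) and photons/um^2/ms for steps (which persist to the
    end of the trace). Dark events carry negative amplitude.
    """

    onset: float
    amplitude: float
    duration: float = 10.0
    kind: Literal["flash", "step"] = "flash"


@dataclass(frozen=True)
class PulseProtocol:
    background: float = 0.0
    events: tuple[PulseEvent, ...] = ()

    def __post_init__(self):
        if self.background < 0:
            raise ValueError("background must be nonnegative")
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.onset))
        )


def make_pulse_stimulus(
    protocol: PulseProtocol,
    grid: TimeGrid,
    on_negative: Literal["clip", "error"] = "clip",
) -> StimulusTrace:
    """Render a background plus flash/step events on the grid.

    Flash boxcars are scaled so their time integral equals the requested
    photon count exactly on the discrete grid. A dark event deeper than the
    available intensity is floored at zero with a warning (or raises with
    ``on_negative="error"``).
    """
    dt = grid.dt
    x = np.full(grid.n, float(protocol.background))
    for ev in protocol.events:
        if ev.duration < dt:
            raise ValueError(f"event duration {ev.duration} ms below grid dt={dt} ms")
        i0 = max(0, int(round((ev.onset - grid.t0) / dt)))
        if ev.kind == "flash":
            nsamp = max(1, int(round(ev.duration / dt)))
            i1 = min(grid.n, i0 + nsamp)
            if i1 > i0:
                x[i0:i1] += ev.amplitude / (nsamp * dt)
        elif ev.kind == "step":
            x[i0:] += ev.amplitude
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    if np.any(x < 0):
        n_neg = int(np.sum(x < 0))
        if on_negative == "error":
            raise ValueError(f"{n_neg} samples driven below zero by dark events")
        warnings.warn(f"clipped {n_neg} negative samples to zero", stacklevel=2)
        x = np.maximum(x, 0.0)
    meta = {
        "generator": "pulse",
        "background": protocol.background,
        "events": [
            {"onset": e.onset, "amplitude": e.amplitude,
             "duration": e.duration, "kind": e.kind}
            for e in protocol.events
        ],
    }
    return StimulusTrace(grid, x, meta)


def flash_on_background(
    I_B: float,
    photons: float,
    grid: TimeGrid,
    onset: float = 0.0,
    duration: float = 10.0,
) -> StimulusTrace:
    """Convenience: one flash of given integrated photons on a constant background."""
    proto = PulseProtocol(background=I_B,
                          events=(PulseEvent(onset, photons, duration, "flash"),))
    return make_pulse_stimulus(proto, grid)


def make_sinusoid_stimulus(
    I_B: float, contrast: float, freq_hz: float, grid: TimeGrid
) -> StimulusTrace:
    """I(t) = I_B (1 + contrast sin(2 pi f t)).

    Contrast is the fractional maximum deviation from the mean; contrast 1
    grazes zero intensity and larger values would require negative light.
    """
    if not 0 <= contrast <= 1:
        raise ValueError(f"contrast must be in [0, 1], got {contrast}")
    if freq_hz < 0:
        raise ValueError("frequency must be nonnegative")
    period_ms = np.inf if freq_hz == 0 else 1000.0 / freq_hz
    if period_ms < 10 * grid.dt:
        raise ValueError(f"{freq_hz} Hz unresolvable at dt={grid.dt} ms")
    t = grid.times
    x = I_B * (1.0 + contrast * np.sin(2e-3 * np.pi * freq_hz * t))
    x = np.maximum(x, 0.0)  # guards rounding at contrast == 1
    return StimulusTrace(
        grid, x,
        {"generator": "sinusoid", "I_B": I_B, "contrast": contrast, "freq_hz": freq_hz},
    )


# --------------------------------------------------------------------------
# Gaussian flicker


@dataclass(frozen=True)
class FlickerSpec:
    """Gaussian flicker description.

    ``sigma`` is the per-sample standard deviation as a *fraction of the
    mean* (e.g. 0.35 for the common 35%-contrast protocol) unless
    ``sigma_absolute`` is set. ``correlation`` selects either a frame-hold
    process (a new Gaussian value held for ``hold_ms``, emulating a CRT
    updated every couple of frames) or an exponentially correlated
    (Ornstein-Uhlenbeck) process with correlation time ``tau_c_ms`` and
    autocorrelation exp(-|lag| / tau_c).

    ``envelope`` optionally modulates sigma over time: a callable t ->
    multiplier, evaluated in ms. ``clip`` is "zero" (floor negative draws
    at zero; the physical default), "none" (allow negative intensities —
    for validating Gaussian closed forms, which assume no clipping), or
    "error".
    """

    mean: float
    sigma: float
    correlation: Literal["hold", "exponential"] = "hold"
    hold_ms: float = 1000.0 / 67.0 * 2  # two frames at 67 Hz
    tau_c_ms: float = 200.0
    seed: int = 0
    sigma_absolute: bool = False
    clip: Literal["zero", "none", "error"] = "zero"
    envelope: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, compare=False
    )

    def __post_init__(self):
        if self.mean < 0 or self.sigma < 0:
            raise ValueError("mean and sigma must be nonnegative")
        if self.correlation == "hold" and self.hold_ms <= 0:
            raise ValueError("hold_ms must be positive")
        if self.correlation == "exponential" and self.tau_c_ms <= 0:
            raise ValueError("tau_c_ms must be positive")


def square_wave_envelope(period_ms: float, low: float, high: float,
                         high_first: bool = True) -> Callable[[np.ndarray], np.ndarray]:
    """Envelope multiplier alternating between ``high`` and ``low`` each
    half-period (values are absolute sigma fractions replacing the spec's
    base sigma of 1)."""

    def env(t: np.ndarray) -> np.ndarray:
        phase = np.mod(t, period_ms) / period_ms
        first, second = (high, low) if high_first else (low, high)
        return np.where(phase < 0.5, first, second)

    return env


def standard_normal_sequence(spec: FlickerSpec, grid: TimeGrid) -> np.ndarray:
    """The unit-variance correlated noise xi(t) underlying the flicker."""
    rng = np.random.default_rng(spec.seed)
    dt = grid.dt
    if spec.correlation == "hold":
        hold = max(1, int(round(spec.hold_ms / dt)))
        ndraws = grid.n // hold + 2
        draws = rng.standard_normal(ndraws)
        xi = np.repeat(draws, hold)[: grid.n]
    elif spec.correlation == "exponential":
        rho = np.exp(-dt / spec.tau_c_ms)
        innov = rng.standard_normal(grid.n)
        xi = np.empty(grid.n)
        xi[0] = innov[0]  # stationary start
        s = np.sqrt(1.0 - rho * rho)
        for k in range(1, grid.n):
            xi[k] = rho * xi[k - 1] + s * innov[k]
    else:
        raise ValueError(f"unknown correlation model {spec.correlation!r}")
    return xi


def make_gaussian_flicker(spec: FlickerSpec, grid: TimeGrid) -> StimulusTrace:
    """Seeded Gaussian flicker around ``spec.mean``.

    The long-run sample mean and standard deviation converge to the spec
    values (before clipping); clip events are counted in the metadata.
    """
    xi = standard_normal_sequence(spec, grid)
    scale = 1.0 if spec.sigma_absolute else spec.mean
    if spec.envelope is not None:
        # the envelope supplies sigma(t) directly (same units as spec.sigma)
        sig_t = scale * np.asarray(spec.envelope(grid.times), dtype=float)
    else:
        sig_t = np.full(grid.n, scale * spec.sigma)
    x = spec.mean + sig_t * xi
    n_neg = int(np.sum(x < 0))
    if n_neg and spec.clip == "error":
        raise ValueError(f"{n_neg} negative flicker samples with clip='error'")
    meta = {
        "generator": "gaussian_flicker",
        "mean": spec.mean,
        "sigma": spec.sigma,
        "sigma_absolute": spec.sigma_absolute,
        "correlation": spec.correlation,
        "hold_ms": spec.hold_ms,
        "tau_c_ms": spec.tau_c_ms,
        "seed": spec.seed,
        "clip": spec.clip,
        "clip_events": n_neg if spec.clip == "zero" else 0,
    }
    if spec.clip == "zero":
        x = np.maximum(x, 0.0)
    else:
        meta["allow_negative"] = True
    return StimulusTrace(grid, x, meta)


def flicker_autocorrelation(spec: FlickerSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Normalized temporal correlation C(lag) of the flicker (C(0) = 1)."""
    if spec.correlation == "exponential":
        tau = spec.tau_c_ms
        return lambda lag: np.exp(-np.abs(lag) / tau)
    hold = spec.hold_ms
    # piecewise-constant frames with random phase: triangular correlation
    return lambda lag: np.maximum(0.0, 1.0 - np.abs(lag) / hold)


# --------------------------------------------------------------------------
# naturalistic surrogate


def make_naturalistic_surrogate(
    seed: int,
    duration: float,
    mean: float,
    grid: Optional[TimeGrid] = None,
    dt: float = 1.0,
    tau_fast_ms: float = 30.0,
    tau_slow_ms: float = 1500.0,
    log_sigma: float = 1.05,
) -> StimulusTrace:
    """Synthetic stand-in for a naturalistic light-intensity time series.

    The generator exponentiates the sum of two Ornstein-Uhlenbeck processes
    (correlation times ~30 ms and ~1.5 s) and rescales to the target mean.
    It emulates the two stated statistical properties of natural intensity
    series — variation over close to three orders of magnitude, on scales
    from tens of milliseconds to seconds — and nothing finer (no spatial
    structure, no 1/f spectrum, no occlusion events). It is a synthetic
    surrogate, not a reproduction of any recorded series.

    With the default per-component log-sigma of 1.05 the stationary
    1st-99th percentile range is 2 * 2.326 * sqrt(2) * 1.05 / ln(10) ~ 3.0
    decades.
    """
    if duration < 10_000:
        warnings.warn("surrogate shorter than 10 s poorly samples the slow scale",
                      stacklevel=2)
    if grid is None:
        grid = TimeGrid.from_duration(duration, dt)
    rng = np.random.default_rng(seed)
    n = grid.n
    logx = np.zeros(n)
    for tau in (tau_fast_ms, tau_slow_ms):
        rho = np.exp(-grid.dt / tau)
        s = np.sqrt(1 - rho * rho)
        innov = rng.standard_normal(n)
        u = np.empty(n)
        u[0] = innov[0]
        for k in range(1, n):
            u[k] = rho * u[k - 1] + s * innov[k]
        logx += log_sigma * u
    x = np.exp(logx)
    x *= mean / np.mean(x)
    return StimulusTrace(
        grid, x,
        {"generator": "naturalistic_surrogate", "seed": seed, "mean": mean,
         "tau_fast_ms": tau_fast_ms, "tau_slow_ms": tau_slow_ms,
         "log_sigma": log_sigma, "synthetic": True},
    )


# --------------------------------------------------------------------------
# probe superposition


def superimpose_probes(
    base: StimulusTrace,
    photons: float,
    times: Sequence[float],
    duration: float = 10.0,
) -> StimulusTrace:
    """Add boxcar probe flashes (integrated ``photons`` each) to a base trace.

    Designed for the paired-run subtraction workflow: simulate the base and
    the probed stimulus, subtract, and read off the incremental (probe)
    responses, whose amplitudes report the instantaneous gain along the
    background's history.
    """
    grid = base.grid
    x = base.intensity.copy()
    times = sorted(times)
    for a, b in zip(times, times[1:]):
        if b - a < duration:
            warnings.warn(f"probes at {a} and {b} ms overlap (duration {duration} ms)",
                          stacklevel=2)
    nsamp = max(1, int(round(duration / grid.dt)))
    for t in times:
        i0 = grid.index_of(t)
        i1 = min(grid.n, i0 + nsamp)
        x[i0:i1] += photons / (nsamp * grid.dt)
    meta = dict(base.metadata)
    meta.update({"probes": {"photons": photons, "times": list(times),
                            "duration": duration}})
    return StimulusTrace(grid, x, meta)


def constant_stimulus(I_B: float, grid: TimeGrid) -> StimulusTrace:
    return StimulusTrace(grid, np.full(grid.n, float(I_B)),
                         {"generator": "constant", "I_B": I_B})
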