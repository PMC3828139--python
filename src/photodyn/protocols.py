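"""End-to-end experiment protocols: stimulus families -> model -> summary tables.

Each protocol is reproducible from its serialized configuration and
seeds, and emits plain tables (dicts of numpy arrays / pandas frames)
that a plotting layer may consume.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .analytics import fit_weber_law, weber_sensitivity_curve
from .grid import TimeGrid
from .kernels import build_kernels
from .model import simulate_da, steady_state_response
from .params import ModelParams, load_paramset
from .stimuli import (
    FlickerSpec,
    PulseEvent,
    PulseProtocol,
    constant_stimulus,
    flash_on_background,
    make_gaussian_flicker,
    make_naturalistic_surrogate,
    make_pulse_stimulus,
    square_wave_envelope,
    superimpose_probes,
)


@dataclass
class ExperimentConfig:
    """Serializable protocol configuration."""

    protocol: str
    paramset: str = "bhl"
    seed: int = 0
    dt: float = 0.1
    options: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))

    def load_params(self) -> ModelParams:
        return load_paramset(self.paramset)


def refined_peak(times: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """(peak hyperpolarization magnitude, peak time) with parabolic sub-grid
    refinement around the discrete extremum."""
    i = int(np.argmin(r))
    if 0 < i < len(r) - 1:
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            off = 0.5 * (y0 - y2) / denom
            off = float(np.clip(off, -1, 1))
            dt = times[1] - times[0]
            t_pk = times[i] + off * dt
            r_pk = y1 - 0.25 * (y0 - y2) * off
            return float(-r_pk), float(t_pk)
    return float(-r[i]), float(times[i])


def local_minima(r: np.ndarray, prominence_frac: float = 0.02) -> np.ndarray:
    """Indices of local minima of r with prominence above a fraction of the range."""
    from scipy.signal import find_peaks

    prom = prominence_frac * float(np.ptp(r))
    peaks, _ = find_peaks(-r, prominence=prom)
    return peaks


# --------------------------------------------------------------------------


def run_flash_family(
    params: ModelParams,
    flash_photons: Sequence[float],
    I_B: float = 0.0,
    flash_duration: float = 10.0,
    dt: float = 0.1,
    window: float = 1500.0,
    pre: float = 100.0,
) -> dict:
    """Flash-intensity series: peak amplitude and peak delay per flash.

    Against darkness the peak amplitude grows linearly, then sub-linearly,
    and saturates near alpha/beta; the peak delay keeps decreasing even
    after the amplitude has saturated.
    """
    grid = TimeGrid.from_duration(pre + window, dt, t0=-pre)
    kernels = build_kernels(params, grid)
    amps, delays, traces = [], [], []
    for F in flash_photons:
        stim = flash_on_background(I_B, F, grid, onset=0.0, duration=flash_duration)
        resp = simulate_da(stim, params, kernels=kernels)
        base = steady_state_response(I_B, params)
        rel = resp.response - base
        sel = grid.times >= 0
        amp, t_pk = refined_peak(grid.times[sel], rel[sel])
        amps.append(amp)
        delays.append(t_pk)
        traces.append(resp)
    return {
        "flash_photons": np.asarray(flash_photons, float),
        "peak_mv": np.asarray(amps),
        "peak_delay_ms": np.asarray(delays),
        "traces": traces,
        "grid": grid,
    }


def baylor_flash_series(n: int = 15, lo: float = 41.0, factor: float = 2.1) -> np.ndarray:
    """Geometric flash series from 41 photons/um^2 in steps of 2.1 (the
    classic turtle-cone protocol spans up to 6.7e5)."""
    return lo * factor ** np.arange(n)


def run_paired_flash(
    params: ModelParams,
    delays_ms: Sequence[float],
    photons: float = 5.6e4,
    flash_duration: float = 10.0,
    dt: float = 0.5,
    window: float = 2500.0,
) -> dict:
    """Conditioning/test flash pairs: normalized incremental test response
    against the (signed) delay of the test flash.

    The incremental response is the paired-flash response minus the
    response to the conditioning flash alone, normalized by the peak of
    the conditioning-alone response; it dips below one for test flashes
    within a few hundred ms of the conditioning flash — on either side,
    since a later conditioning flash still overlaps the extended test
    response.
    """
    pre = 500.0 + max(0.0, -min(delays_ms))
    grid = TimeGrid.from_duration(pre + window, dt, t0=-pre)
    kernels = build_kernels(params, grid)
    cond = flash_on_background(0.0, photons, grid, onset=0.0, duration=flash_duration)
    r_cond = simulate_da(cond, params, kernels=kernels).response
    peak_cond, _ = refined_peak(grid.times, r_cond)
    norm = []
    for d in delays_ms:
        proto = PulseProtocol(0.0, (
            PulseEvent(0.0, photons, flash_duration, "flash"),
            PulseEvent(float(d), photons, flash_duration, "flash"),
        ))
        stim = make_pulse_stimulus(proto, grid)
        r_pair = simulate_da(stim, params, kernels=kernels).response
        inc = r_pair - r_cond
        amp, _ = refined_peak(grid.times, inc)
        norm.append(amp / peak_cond)
    return {"delay_ms": np.asarray(delays_ms, float),
            "normalized_incremental_peak": np.asarray(norm)}


def run_step_family(
    params: ModelParams,
    step_intensities: Sequence[float],
    I_B: float = 0.0,
    dt: float = 0.5,
    window: float = 4000.0,
) -> dict:
    """Steps (bright, or dark when negative) on a background: peak and
    steady-state hyperpolarization per step."""
    grid = TimeGrid.from_duration(500.0 + window, dt, t0=-500.0)
    kernels = build_kernels(params, grid)
    peaks, steadies = [], []
    base = steady_state_response(I_B, params)
    for A in step_intensities:
        proto = PulseProtocol(I_B, (PulseEvent(0.0, float(A), 10.0, "step"),))
        stim = make_pulse_stimulus(proto, grid)
        r = simulate_da(stim, params, kernels=kernels).response - base
        sel = grid.times >= 0
        i_ext = int(np.argmax(np.abs(r[sel])))
        peaks.append(float(r[sel][i_ext]))
        steadies.append(float(r[-1]))
    return {
        "step_intensity": np.asarray(step_intensities, float),
        "peak_mv": np.asarray(peaks),
        "steady_mv": np.asarray(steadies),
    }


def run_background_protocols(
    params: ModelParams,
    backgrounds: Sequence[float],
    probe_photons: float = 100.0,
    dt: float = 0.5,
) -> dict:
    """Flash-on-background family: peak delay vs background, Weber curve.

    The delay of the peak response to a fixed flash decreases with
    background intensity and then saturates (the bright-limit response
    shape, and hence its peak time, is background-independent).
    """
    grid = TimeGrid.from_duration(1500.0, dt, t0=-100.0)
    kernels = build_kernels(params, grid)
    delays, amps = [], []
    for I_B in backgrounds:
        stim = flash_on_background(I_B, probe_photons, grid, onset=0.0,
                                   duration=10.0)
        base = constant_stimulus(I_B, grid)
        r = (simulate_da(stim, params, kernels=kernels).response
             - simulate_da(base, params, kernels=kernels).response)
        sel = grid.times >= 0
        amp, t_pk = refined_peak(grid.times[sel], r[sel])
        delays.append(t_pk)
        amps.append(amp)
    sens = weber_sensitivity_curve(params, backgrounds, dt=max(dt, 0.5))
    weber = fit_weber_law(np.asarray(backgrounds, float), sens)
    return {
        "backgrounds": np.asarray(backgrounds, float),
        "flash_peak_mv": np.asarray(amps),
        "flash_delay_ms": np.asarray(delays),
        "weber_sensitivity": sens,
        "weber_fit": weber,
    }


def run_compressive_flash_pair(
    params: ModelParams,
    I_B: float,
    weak_photons: float,
    ratio: float = 400.0,
    flash_duration: float = 1.0,
    dt: float = 0.1,
    window: float = 1200.0,
) -> dict:
    """Two flashes differing ``ratio``-fold on the same bright background.

    On bright backgrounds the response is strongly compressive: the peak
    responses differ far less than the flash strengths do. Returns the two
    peak magnitudes and their ratio.
    """
    grid = TimeGrid.from_duration(300.0 + window, dt, t0=-300.0)
    kernels = build_kernels(params, grid)
    base = constant_stimulus(I_B, grid)
    r0 = simulate_da(base, params, kernels=kernels).response
    out = {}
    for name, F in (("weak", weak_photons), ("strong", ratio * weak_photons)):
        stim = flash_on_background(I_B, F, grid, onset=0.0, duration=flash_duration)
        r = simulate_da(stim, params, kernels=kernels).response - r0
        sel = grid.times >= 0
        amp, _ = refined_peak(grid.times[sel], r[sel])
        out[name] = amp
    out["peak_ratio"] = out["strong"] / out["weak"]
    out["flash_ratio"] = ratio
    return out


def run_probe_ensemble(
    params: ModelParams,
    seed: int = 0,
    mean: float = 100.0,
    probe_photons: float = 100.0,
    duration_s: float = 60.0,
    dt: float = 1.0,
    n_probes: int = 120,
    probe_duration: float = 10.0,
) -> dict:
    """Probe flashes on a naturalistic surrogate background.

    Simulates the background alone and with superimposed probes, and
    measures each probe's incremental peak response (subtraction
    workflow). Also computes the same probe on a constant mean-matched
    background. The spread of probe amplitudes and the offset of their
    mean relative to the constant-background case are the signatures of
    fast dynamical adaptation.
    """
    base = make_naturalistic_surrogate(seed, duration_s * 1000.0, mean, dt=dt)
    grid = base.grid
    kernels = build_kernels(params, grid)
    start = 2000.0
    spacing = (grid.t_end - start - 1000.0) / n_probes
    if spacing < 600.0:
        raise ValueError("probes closer than 600 ms would overlap in response")
    times = start + spacing * np.arange(n_probes)
    probed = superimpose_probes(base, probe_photons, times, duration=probe_duration)
    r_base = simulate_da(base, params, kernels=kernels).response
    r_probe = simulate_da(probed, params, kernels=kernels).response
    inc = r_probe - r_base
    n_win = int(round(500.0 / dt))
    peaks = np.empty(n_probes)
    for i, t in enumerate(times):
        i0 = grid.index_of(t)
        seg = inc[i0 : i0 + n_win]
        peaks[i] = -float(np.min(seg))
    # constant mean-matched reference
    ref_grid = TimeGrid.from_duration(2000.0, dt, t0=-500.0)
    ref_kern = build_kernels(params, ref_grid)
    ref_stim = flash_on_background(mean, probe_photons, ref_grid, onset=0.0,
                                   duration=probe_duration)
    ref_base = constant_stimulus(mean, ref_grid)
    ref_inc = (simulate_da(ref_stim, params, kernels=ref_kern).response
               - simulate_da(ref_base, params, kernels=ref_kern).response)
    ref_peak = -float(np.min(ref_inc))
    return {
        "probe_times": times,
        "probe_peaks_mv": peaks,
        "constant_background_peak_mv": ref_peak,
        "p1": float(np.percentile(peaks, 1)),
        "p99": float(np.percentile(peaks, 99)),
        "mean_peak_mv": float(np.mean(peaks)),
    }


def run_variance_switch(
    params: ModelParams,
    mean: float = 150.0,
    sigma_high: float = 0.35,
    sigma_low: float = 0.05,
    period_ms: float = 1000.0,
    n_replicates: int = 200,
    seed: int = 0,
    dt: float = 2.0,
    n_periods: int = 3,
) -> dict:
    """Mean response to flicker whose s.d. switches periodically.

    Averages seeded runs; the mean trace shows a depolarizing overshoot
    when the variance steps up and a hyperpolarizing undershoot when it
    steps down, and a less hyperpolarized quasi-steady level during the
    high-variance half-period.
    """
    env = square_wave_envelope(period_ms, low=sigma_low, high=sigma_high)
    warm = 2000.0
    grid = TimeGrid.from_duration(warm + n_periods * period_ms, dt, t0=-warm)
    kernels = build_kernels(params, grid)
    rng = np.random.default_rng(seed)
    acc = np.zeros(grid.n)
    acc2 = np.zeros(grid.n)
    for _ in range(n_replicates):
        spec = FlickerSpec(mean=mean, sigma=sigma_high, correlation="hold",
                           hold_ms=30.0, seed=int(rng.integers(2**31 - 1)),
                           envelope=env)
        stim = make_gaussian_flicker(spec, grid)
        r = simulate_da(stim, params, kernels=kernels).response
        acc += r
        acc2 += r * r
    mean_r = acc / n_replicates
    sem = np.sqrt(np.maximum(acc2 / n_replicates - mean_r**2, 0) / n_replicates)
    return {"grid": grid, "mean_response": mean_r, "sem": sem,
            "period_ms": period_ms, "envelope": env}


def run_protocol(config: ExperimentConfig) -> dict:
    """Dispatch a named protocol from a config (CLI entry point)."""
    p = config.load_params()
    opts = dict(config.options)
    name = config.protocol
    if name == "flash_family":
        series = opts.pop("flash_photons", baylor_flash_series().tolist())
        res = run_flash_family(p, series, dt=config.dt, **opts)
        res.pop("traces")
        res.pop("grid")
        return res
    if name == "paired_flash":
        delays = opts.pop("delays_ms", np.arange(-600, 601, 50).tolist())
        return run_paired_flash(p, delays, dt=max(config.dt, 0.5), **opts)
    if name == "background":
        bgs = opts.pop("backgrounds", np.geomspace(1e-3, 1e4, 22).tolist())
        return run_background_protocols(p, bgs, dt=max(config.dt, 0.5), **opts)
    if name == "variance_switch":
        return {k: v for k, v in run_variance_switch(
            p, seed=config.seed, **opts).items() if k not in ("grid", "envelope")}
    if name == "probe_ensemble":
        return run_probe_ensemble(p, seed=config.seed, **opts)
    raise ValueError(f"unknown protocol {name!r}")
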