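"""Linear-Nonlinear (LN) baseline and dynamical-gain diagnostics.

The LN cascade — a causal linear filter estimated by reverse correlation,
followed by a static polynomial nonlinearity — is the standard model
against which dynamical adaptation is judged. A photoreceptor whose gain
and kinetics track the recent input history is systematically mis-fit by
any static nonlinearity; the diagnostics here quantify that failure:

* instantaneous gain — the local slope of the observed response against
  the model's (linear) prediction over short flanking windows;
* history-conditioned ("corrective") gains — slopes computed separately
  for times whose preceding-300-ms mean intensity is in the dimmest or
  brightest decile;
* percentile-group filters and peak cross-correlation timing — how the
  effective filter's amplitude and latency co-vary with the gain;
* a circular-shift Monte-Carlo test for the significance of any such
  statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import fftconvolve

from .traces import ResponseTrace, StimulusTrace


@dataclass
class LNModel:
    """Causal linear filter (1/ms scale) + static degree-3 polynomial."""

    dt: float
    filter: np.ndarray            # taps at lags 0, dt, 2dt, ...
    poly_coeffs: np.ndarray       # highest degree first (np.polyval order)
    stim_mean: float
    residual_rms: float = np.nan  # in units of response s.d.
    r_squared: float = np.nan

    @property
    def filter_ms(self) -> float:
        return self.dt * len(self.filter)

    @property
    def lags(self) -> np.ndarray:
        return self.dt * np.arange(len(self.filter))


@dataclass
class GainProfile:
    """Windowed instantaneous-gain summary along a trace."""

    times: np.ndarray                  # window centers, ms
    gains: np.ndarray                  # per-window mean instantaneous gain
    mean_preceding_intensity: np.ndarray
    window_ms: float = 300.0
    stride_ms: float = 100.0
    flank_ms: float = 150.0


def _lagged_matrix(x: np.ndarray, n_taps: int) -> np.ndarray:
    """Design matrix X[t, k] = x[t - k] with zero pre-history."""
    n = len(x)
    X = np.zeros((n, n_taps))
    for k in range(n_taps):
        X[k:, k] = x[: n - k]
    return X


def estimate_ln(
    stim: StimulusTrace,
    resp: ResponseTrace,
    filter_ms: float = 500.0,
    degree: int = 3,
    ridge: str | float = "gcv",
) -> LNModel:
    """Fit the LN model by whitened cross-correlation (ridge least squares).

    The filter solves min ||r - X w||^2 + lam ||w||^2 over causal lags up
    to ``filter_ms``, with ``lam`` chosen by generalized cross-validation
    (pass ``ridge=0`` for the plain least-squares / white-input estimate,
    or a number to fix it). The static nonlinearity is an ordinary
    least-squares polynomial of the requested degree fitted between the
    linear prediction and the response.
    """
    if stim.grid != resp.grid:
        raise ValueError("stimulus and response must share a grid")
    dt = stim.grid.dt
    n_taps = int(round(filter_ms / dt))
    if stim.grid.n < 3 * n_taps:
        raise ValueError("trace too short relative to the filter duration")
    x = stim.intensity - stim.intensity.mean()
    r = resp.response
    if np.std(x) == 0:
        raise ValueError("stimulus has zero variance; filter is unidentifiable")
    X = _lagged_matrix(x, n_taps)
    # drop the warm-up rows that mix in the artificial zero pre-history
    Xv, rv = X[n_taps:], r[n_taps:]
    U, s, Vt = np.linalg.svd(Xv, full_matrices=False)
    Ur = U.T @ rv
    if ridge == "gcv":
        lams = np.concatenate([[0.0], np.geomspace(1e-8, 1e4, 25) * s[0] ** 2])
        best, lam_best = np.inf, 0.0
        n_rows = Xv.shape[0]
        for lam in lams:
            shrink = s**2 / (s**2 + lam)
            res = rv - U @ (shrink * Ur)
            dof = n_rows - np.sum(shrink)
            g = (np.sum(res**2) / n_rows) / (dof / n_rows) ** 2
            if g < best:
                best, lam_best = g, lam
        lam = lam_best
    else:
        lam = float(ridge)
    w = Vt.T @ (s / (s**2 + lam) * Ur)

    lin = X @ w
    coeffs = np.polyfit(lin[n_taps:], rv, degree)
    pred = np.polyval(coeffs, lin[n_taps:])
    resid = rv - pred
    sd = np.std(rv)
    model = LNModel(
        dt=dt,
        filter=w / dt,  # store on a 1/ms scale so predict re-multiplies by dt
        poly_coeffs=coeffs,
        stim_mean=float(stim.intensity.mean()),
        residual_rms=float(np.std(resid) / sd),
        r_squared=float(1.0 - np.var(resid) / np.var(rv)),
    )
    return model


def ln_predict(model: LNModel, stim: StimulusTrace) -> ResponseTrace:
    """Evaluate the LN cascade on a stimulus (filter, then pointwise poly)."""
    if abs(stim.grid.dt - model.dt) > 1e-9 * model.dt:
        raise ValueError(f"stimulus dt={stim.grid.dt} does not match model dt={model.dt}")
    lin = linear_prediction(model, stim)
    out = np.polyval(model.poly_coeffs, lin)
    return ResponseTrace(stim.grid, out, metadata={"method": "ln_predict"})


def linear_prediction(model: LNModel, stim: StimulusTrace) -> np.ndarray:
    """The filtered (pre-nonlinearity) signal, dt * conv(filter, x)."""
    x = stim.intensity - model.stim_mean
    return fftconvolve(x, model.filter)[: stim.grid.n] * model.dt


def instantaneous_gain_series(
    stim: StimulusTrace,
    resp: ResponseTrace,
    model: LNModel,
    window_ms: float = 300.0,
    stride_ms: float = 100.0,
    flank_ms: float = 150.0,
    preceding_ms: float = 300.0,
) -> GainProfile:
    """Windowed instantaneous gain along the trace.

    At each evaluation time the instantaneous gain is the OLS slope of the
    scatter of the response against the linear prediction over the
    ``flank_ms`` windows flanking that time; gains are averaged within
    ``window_ms`` windows spaced every ``stride_ms``, and each window is
    paired with the mean intensity over the ``preceding_ms`` before its
    center. Windows whose linear prediction has (near-)zero variance get
    NaN gains rather than raising.
    """
    grid = stim.grid
    dt = grid.dt
    lin = linear_prediction(model, stim)
    r = resp.response
    n_flank = int(round(flank_ms / dt))
    n_prec = int(round(preceding_ms / dt))
    stride = max(1, int(round(stride_ms / dt)))
    start = int(round(model.filter_ms / dt)) + n_flank
    centers = np.arange(start, grid.n - n_flank, stride)
    gains = np.full(len(centers), np.nan)
    prec = np.full(len(centers), np.nan)
    var_floor = 1e-12 * np.var(lin)
    for j, c in enumerate(centers):
        sl = slice(c - n_flank, c + n_flank + 1)
        lv = lin[sl]
        v = np.var(lv)
        if v <= var_floor:
            continue
        gains[j] = np.cov(lv, r[sl], bias=True)[0, 1] / v
        p0 = max(0, c - n_prec)
        prec[j] = np.mean(stim.intensity[p0:c])
    return GainProfile(
        times=grid.times[centers],
        gains=gains,
        mean_preceding_intensity=prec,
        window_ms=window_ms,
        stride_ms=stride_ms,
        flank_ms=flank_ms,
    )


@dataclass
class GroupedGainResult:
    """Percentile-group summaries of the gain profile."""

    group_edges: np.ndarray          # gain percentiles delimiting the groups
    peak_corr_times: np.ndarray      # ms, per group
    group_filters: np.ndarray        # (n_groups, n_lags) averaged cross-correlations
    filter_lags: np.ndarray
    dim_slope: float = np.nan        # corrective gain after dim history
    bright_slope: float = np.nan     # corrective gain after bright history
    group_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    reliable: bool = True


def _window_crosscorr(
    stim_x: np.ndarray, r: np.ndarray, centers: np.ndarray, half: int, n_lags: int
) -> np.ndarray:
    """Zero-padded per-window cross-correlations of stimulus with response.

    Returns one row per window center: xc[lag] = sum_t r(t) x(t - lag)
    over the window, for lags 0..n_lags-1.
    """
    rows = np.zeros((len(centers), n_lags))
    n = len(r)
    for i, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        rw = r[lo:hi] - np.mean(r[lo:hi])
        for lag in range(n_lags):
            xlo, xhi = lo - lag, hi - lag
            if xlo < 0:
                continue
            xw = stim_x[xlo:xhi]
            rows[i, lag] = np.dot(rw, xw)
    return rows


def grouped_gain_analysis(
    profile: GainProfile,
    stim: StimulusTrace,
    resp: ResponseTrace,
    model: LNModel,
    n_groups: int = 10,
    percentile: float = 0.10,
    filter_ms: float = 300.0,
    min_group: int = 30,
) -> GroupedGainResult:
    """Percentile-group structure of the instantaneous gain.

    * Splits the windowed gains into ``n_groups`` percentile groups; for
      each group averages the zero-padded window cross-correlations of
      stimulus with response and takes the mean of the top-10 peak-lag
      times as the group's peak correlation time. On adapting data the
      peak time increases with gain (high gain <-> slow response).
    * Computes corrective-gain slopes of response vs. model prediction for
      the times whose preceding-intensity is in the dimmest and brightest
      ``percentile`` deciles. On adapting data predicted linearly, the dim
      slope exceeds the bright slope.
    """
    grid = stim.grid
    dt = grid.dt
    ok = np.isfinite(profile.gains) & np.isfinite(profile.mean_preceding_intensity)
    gains = profile.gains[ok]
    prec = profile.mean_preceding_intensity[ok]
    times = profile.times[ok]
    if len(gains) < n_groups * 3:
        raise ValueError("too few gain windows for grouped analysis")

    order = np.argsort(gains)
    groups = np.array_split(order, n_groups)
    sizes = np.array([len(g) for g in groups])
    reliable = bool(np.all(sizes >= min_group))

    x = stim.intensity - stim.intensity.mean()
    r = resp.response
    half = int(round(profile.window_ms / 2 / dt))
    n_lags = int(round(filter_ms / dt))
    centers_idx = np.array([grid.index_of(t) for t in times])

    peak_times = np.empty(n_groups)
    filters = np.zeros((n_groups, n_lags))
    for gi, g in enumerate(groups):
        rows = _window_crosscorr(x, r, centers_idx[g], half, n_lags)
        avg = rows.mean(axis=0)
        filters[gi] = avg
        # peak lag of the group-averaged cross-correlation, with parabolic
        # sub-grid refinement (group timing differences can be ~ms)
        m = np.abs(avg)
        i = int(np.argmax(m))
        t_pk = dt * i
        if 0 < i < n_lags - 1:
            y0, y1, y2 = m[i - 1], m[i], m[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                t_pk += dt * float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
        peak_times[gi] = t_pk

    # corrective-gain slopes conditioned on preceding intensity
    pred = ln_predict(model, stim).response
    n_prec = int(round(300.0 / dt))
    prec_t = np.full(grid.n, np.nan)
    csum = np.concatenate([[0.0], np.cumsum(stim.intensity)])
    idx = np.arange(n_prec, grid.n)
    prec_t[idx] = (csum[idx] - csum[idx - n_prec]) / n_prec
    valid = np.isfinite(prec_t)
    valid[: int(round(model.filter_ms / dt))] = False
    qlo, qhi = np.nanquantile(prec_t[valid], [percentile, 1.0 - percentile])
    dim_mask = valid & (prec_t <= qlo)
    bright_mask = valid & (prec_t >= qhi)

    def slope(mask: np.ndarray) -> float:
        p, q = pred[mask], r[mask]
        vp = np.var(p)
        if vp == 0:
            return np.nan
        return float(np.cov(p, q, bias=True)[0, 1] / vp)

    return GroupedGainResult(
        group_edges=np.quantile(gains, np.linspace(0, 1, n_groups + 1)),
        peak_corr_times=peak_times,
        group_filters=filters,
        filter_lags=dt * np.arange(n_lags),
        dim_slope=slope(dim_mask),
        bright_slope=slope(bright_mask),
        group_sizes=sizes,
        reliable=reliable,
    )


def history_conditioned_slopes(
    stim: StimulusTrace,
    resp: ResponseTrace,
    prediction: np.ndarray,
    percentile: float = 0.10,
    preceding_ms: float = 300.0,
    skip_ms: float = 500.0,
) -> tuple[float, float]:
    """(dim-history slope, bright-history slope) of response vs prediction.

    Scatter points are conditioned on the mean stimulus intensity over the
    preceding ``preceding_ms`` being in the dimmest or brightest
    ``percentile``. For a model that captures the adaptation, the two
    corrective slopes coincide; for a static model they differ.
    """
    grid = stim.grid
    dt = grid.dt
    n_prec = int(round(preceding_ms / dt))
    csum = np.concatenate([[0.0], np.cumsum(stim.intensity)])
    prec = np.full(grid.n, np.nan)
    idx = np.arange(n_prec, grid.n)
    prec[idx] = (csum[idx] - csum[idx - n_prec]) / n_prec
    valid = np.isfinite(prec)
    valid[: int(round(skip_ms / dt))] = False
    qlo, qhi = np.nanquantile(prec[valid], [percentile, 1.0 - percentile])

    def slope(mask):
        p, q = prediction[mask], resp.response[mask]
        vp = np.var(p)
        return float(np.cov(p, q, bias=True)[0, 1] / vp) if vp > 0 else np.nan

    return slope(valid & (prec <= qlo)), slope(valid & (prec >= qhi))


def circular_shift_pvalue(
    statistic: Callable[[StimulusTrace, ResponseTrace], float],
    stim: StimulusTrace,
    resp: ResponseTrace,
    n_shuffles: int = 3000,
    seed: int = 0,
    exclude_ms: float = 500.0,
) -> float:
    """Two-sided circular-shift Monte-Carlo p-value for a statistic.

    The statistic is re-evaluated ``n_shuffles`` times with the stimulus
    circularly rotated by a random delay (excluding shifts within
    ``exclude_ms`` of zero, which remain trivially correlated through the
    filter), and the p-value is the add-one-corrected frequency of
    shuffled |statistic| values at least as large as the observed one.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    observed = abs(statistic(stim, resp))
    n = stim.grid.n
    excl = int(round(exclude_ms / stim.grid.dt))
    if 2 * excl >= n:
        raise ValueError("trace too short for the shift exclusion window")
    count = 0
    for _ in range(n_shuffles):
        shift = int(rng.integers(excl, n - excl))
        rolled = stim.with_intensity(np.roll(stim.intensity, shift))
        if abs(statistic(rolled, resp)) >= observed:
            count += 1
    return (1 + count) / (1 + n_shuffles)
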