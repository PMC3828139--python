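"""Least-squares estimation of DA-model parameters and fit diagnostics.

The goodness-of-fit is

    Q = 1 - sum_traces sum_t (pred - obs)^2 / sum_traces n_t * var(obs_t),

i.e. the total squared error normalized by the summed (count-weighted)
variances of the observation traces; Q = 1 for a perfect fit and Q = 0
for a predictor no better than each trace's mean.

Fitting minimizes the squared error with a bounded quasi-Newton local
search (scipy ``least_squares``, trust-region reflective, finite-
difference gradients) over any subset of the eight parameters, optionally
with a multi-start around the initial guess. Parameters are optimized in
log space (all are positive scale/shape quantities) which also encodes
positivity. The kernel shape-time products n_y*tau_y and n_z*tau_z are
the identifiable combinations: n and tau trade off along shallow valleys
of Q, so recovery is assessed on the products.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import simulate_da
from .params import ModelParams
from .traces import ResponseTrace, StimulusTrace

PARAM_NAMES = ("alpha", "beta", "gamma", "tau_r", "n_y", "tau_y", "n_z", "tau_z")

DEFAULT_BOUNDS = {
    "alpha": (1e-4, 1e3),
    "beta": (1e-6, 10.0),
    "gamma": (1e-3, 1.0),
    "tau_r": (0.5, 500.0),
    "n_y": (0.1, 20.0),
    "tau_y": (1.0, 500.0),
    "n_z": (0.1, 30.0),
    "tau_z": (1.0, 500.0),
}


def goodness_of_fit(
    predictions: Sequence[ResponseTrace], observations: Sequence[ResponseTrace]
) -> float:
    """Variance-normalized goodness-of-fit Q over matched trace sets."""
    if len(predictions) != len(observations):
        raise ValueError("prediction and observation sets differ in length")
    sse = 0.0
    svar = 0.0
    for p, o in zip(predictions, observations):
        if p.grid != o.grid:
            raise ValueError("matched traces must share a grid")
        v = float(np.var(o.response))
        if v == 0.0:
            raise ValueError(
                "observation trace has zero variance; Q is undefined for it"
            )
        sse += float(np.sum((p.response - o.response) ** 2))
        svar += v * o.grid.n
    return 1.0 - sse / svar


@dataclass
class FitResult:
    params: ModelParams
    Q: float
    residual_rms: np.ndarray          # per trace, in response-s.d. units
    converged: bool
    n_evaluations: int
    free: tuple[str, ...]
    at_bounds: tuple[str, ...] = ()
    alpha_per_trace: Optional[np.ndarray] = None
    history: dict = field(default_factory=dict)


def _predict_set(
    params: ModelParams, stims: Sequence[StimulusTrace]
) -> list[ResponseTrace]:
    return [simulate_da(s, params) for s in stims]


def _residual_vector(preds, obs) -> np.ndarray:
    return np.concatenate([p.response - o.response for p, o in zip(preds, obs)])


def fit_da_model(
    stims: Sequence[StimulusTrace],
    resps: Sequence[ResponseTrace],
    init: ModelParams,
    free: Sequence[str] = PARAM_NAMES,
    bounds: Optional[dict] = None,
    integer_shapes: bool = False,
    per_trace_alpha: bool = False,
    max_nfev: int = 2000,
    seed: int = 0,
    n_starts: int = 1,
    start_spread: float = 0.3,
) -> FitResult:
    """Bounded least-squares fit of the DA model to stimulus/response pairs.

    Parameters
    ----------
    free : names of the parameters to optimize; the rest stay at ``init``.
    integer_shapes : if True, n_y and n_z are rounded to integers after the
        continuous optimization and the remaining free parameters are
        re-polished with the shapes pinned.
    per_trace_alpha : rescale alpha per trace by the closed-form optimal
        linear gain (accounts for experiment-to-experiment scale changes).
    n_starts : additional random multi-starts, log-uniform within
        ``start_spread`` (fractional) of ``init``; the best Q wins.
    """
    if len(stims) == 0 or len(stims) != len(resps):
        raise ValueError("need at least one matched stimulus/response pair")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    free = tuple(free)
    for name in free:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")

    rng = np.random.default_rng(seed)
    lo = np.log([bounds[f][0] for f in free])
    hi = np.log([bounds[f][1] for f in free])

    def unpack(x: np.ndarray) -> ModelParams:
        kw = {f: float(np.exp(v)) for f, v in zip(free, x)}
        if "gamma" in kw:
            kw["gamma"] = min(kw["gamma"], 1.0)
        return init.replace(**kw)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        preds = _predict_set(p, stims)
        if per_trace_alpha:
            out = []
            for pr, ob in zip(preds, resps):
                denom = float(np.dot(pr.response, pr.response))
                g = float(np.dot(pr.response, ob.response)) / denom if denom > 0 else 1.0
                out.append(g * pr.response - ob.response)
            return np.concatenate(out)
        return _residual_vector(preds, resps)

    x0_base = np.log([np.clip(getattr(init, f), *bounds[f]) for f in free])
    starts = [x0_base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.clip(x0_base + rng.uniform(np.log(1 - start_spread),
                                          np.log(1 + start_spread), len(free)),
                    lo, hi)
        )

    best = None
    total_nfev = 0
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), max_nfev=max_nfev,
                            x_scale="jac", method="trf",
                            ftol=1e-12, xtol=1e-10, gtol=1e-10)
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    if integer_shapes:
        fitted = unpack(best.x)
        pinned = fitted.replace(n_y=float(round(fitted.n_y)),
                                n_z=float(round(fitted.n_z)))
        free2 = tuple(f for f in free if f not in ("n_y", "n_z"))
        if free2:
            sub = fit_da_model(stims, resps, pinned, free=free2, bounds=bounds,
                               per_trace_alpha=per_trace_alpha,
                               max_nfev=max_nfev, seed=seed)
            total_nfev += sub.n_evaluations
            final = sub.params
            converged = sub.converged
        else:
            final, converged = pinned, best.status > 0
    else:
        final = unpack(best.x)
        converged = best.status > 0

    preds = _predict_set(final, stims)
    alpha_scales = None
    if per_trace_alpha:
        alpha_scales = np.array([
            float(np.dot(p.response, o.response) / np.dot(p.response, p.response))
            if np.dot(p.response, p.response) > 0 else 1.0
            for p, o in zip(preds, resps)
        ])
        preds = [ResponseTrace(p.grid, g * p.response)
                 for g, p in zip(alpha_scales, preds)]
    q = goodness_of_fit(preds, resps)
    rms = np.array([
        float(np.std(p.response - o.response) / np.std(o.response))
        for p, o in zip(preds, resps)
    ])
    at_bounds = tuple(
        f for f, v in zip(free, best.x)
        if v <= lo[list(free).index(f)] + 1e-6 or v >= hi[list(free).index(f)] - 1e-6
    )
    return FitResult(
        params=final, Q=q, residual_rms=rms, converged=converged,
        n_evaluations=total_nfev, free=free, at_bounds=at_bounds,
        alpha_per_trace=alpha_scales,
        history={"cost": float(best.cost), "n_starts": len(starts)},
    )


# --------------------------------------------------------------------------
# sensitivity analysis


def q_profile(
    fit: FitResult,
    stims: Sequence[StimulusTrace],
    resps: Sequence[ResponseTrace],
    name: str,
    rel_range: float = 0.3,
    n_points: int = 13,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D profile of Q against one parameter, others held at the optimum."""
    v0 = getattr(fit.params, name)
    values = v0 * np.linspace(1 - rel_range, 1 + rel_range, n_points)
    qs = np.empty(n_points)
    for i, v in enumerate(values):
        p = fit.params.replace(**{name: float(min(v, 1.0) if name == "gamma" else v)})
        qs[i] = goodness_of_fit(_predict_set(p, stims), resps)
    return values, qs


def q_hessian(
    fit: FitResult,
    stims: Sequence[StimulusTrace],
    resps: Sequence[ResponseTrace],
    names: Sequence[str],
    rel_step: float = 0.02,
) -> np.ndarray:
    """Numerical second-derivative matrix of Q at the optimum, in relative
    (fractional) parameter coordinates."""
    k = len(names)
    v0 = np.array([getattr(fit.params, n) for n in names])

    def qat(frac: np.ndarray) -> float:
        kw = {n: float(v) for n, v in zip(names, v0 * (1 + frac))}
        if "gamma" in kw:
            kw["gamma"] = min(kw["gamma"], 1.0)
        return goodness_of_fit(_predict_set(fit.params.replace(**kw), stims), resps)

    H = np.empty((k, k))
    q0 = qat(np.zeros(k))
    h = rel_step
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (qat(ei) - 2 * q0 + qat(-ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                qat(ei + ej) - qat(ei - ej) - qat(-ei + ej) + qat(-ei - ej)
            ) / (4 * h**2)
    return H


def sensitivity_scan(
    fit: FitResult,
    stims: Sequence[StimulusTrace],
    resps: Sequence[ResponseTrace],
    pairs: Sequence[tuple[str, str]],
    rel_range: float = 0.3,
    n_points: int = 13,
) -> dict:
    """1-D profiles and Hessian-based 2-D contour data around the optimum.

    For each requested pair the quadratic form dQ = 1/2 dx^T H dx (x in
    fractional coordinates) yields elliptical contours at chosen Q
    degradations; an indefinite Hessian block triggers a direct grid
    evaluation fallback with a warning flag.
    """
    names = sorted({n for pair in pairs for n in pair})
    profiles = {n: q_profile(fit, stims, resps, n, rel_range, n_points)
                for n in names}
    H = q_hessian(fit, stims, resps, names)
    out = {"profiles": profiles, "hessian": H, "hessian_names": names, "pairs": {}}
    for a, b in pairs:
        ia, ib = names.index(a), names.index(b)
        Hb = H[np.ix_([ia, ib], [ia, ib])]
        eig = np.linalg.eigvalsh(Hb)
        entry = {"hessian_block": Hb, "definite": bool(np.all(eig < 0))}
        if not entry["definite"]:
            grid_a, qa = q_profile(fit, stims, resps, a, rel_range, n_points)
            grid_b, qb = q_profile(fit, stims, resps, b, rel_range, n_points)
            entry["grid_fallback"] = (grid_a, grid_b, qa, qb)
        out["pairs"][(a, b)] = entry
    return out


def identifiable_summary(params: ModelParams) -> dict:
    """The identifiable parameter combinations used for recovery checks."""
    return {
        "alpha": params.alpha,
        "beta": params.beta,
        "gamma": params.gamma,
        "tau_r": params.tau_r,
        "ny_tauy": params.n_y * params.tau_y,
        "nz_tauz": params.n_z * params.tau_z,
    }
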