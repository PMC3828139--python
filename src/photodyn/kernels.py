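"""Temporal kernels of the DA model.

The drive kernel is a causal, unit-area gamma kernel

    Ky(t) = t^{n_y} exp(-t/tau_y) / (Gamma(n_y + 1) tau_y^{n_y + 1}),  t >= 0,

which corresponds to a chain of n_y + 1 first-order relaxation stages and
peaks at t = n_y * tau_y. The gain-control kernel mixes a fast component,
identical to Ky, with a slower gamma kernel:

    Kz(t) = gamma * Ky(t) + (1 - gamma) * Kslow(t),

Kslow being the unit-area gamma kernel with parameters (n_z, tau_z). With
gamma < 1, Kz is broader than Ky and its mass is delayed — the delay is
what turns the divisive gain term into a history-dependent (adaptive)
modulation rather than an instantaneous one.

Both kernels integrate to one; after discretization the sampled kernels
are renormalized so their discrete sums (times dt) are exactly one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .grid import TimeGrid
from .params import ModelParams

TAIL_TOL = 1e-6


def gamma_kernel(t: np.ndarray, n: float, tau: float) -> np.ndarray:
    """Unit-area gamma kernel t^n e^{-t/tau} / (Gamma(n+1) tau^{n+1}) for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    # log-domain evaluation; t=0 with n>0 gives 0, n=0 gives 1/tau
    tp = t[pos]
    with np.errstate(divide="ignore"):
        logk = special.xlogy(n, tp) - tp / tau - special.gammaln(n + 1) - (n + 1) * np.log(tau)
    out[pos] = np.exp(logk)
    return out


def gamma_kernel_tail_mass(T: float, n: float, tau: float) -> float:
    """Analytic mass of the kernel beyond time T (regularized upper gamma)."""
    return float(special.gammaincc(n + 1, T / tau))


def gamma_kernel_support(n: float, tau: float, tol: float = TAIL_TOL) -> float:
    """Smallest T with tail mass below tol."""
    return float(tau * special.gammainccinv(n + 1, tol))


def kernel_support(params: ModelParams, tol: float = TAIL_TOL) -> float:
    """Support length covering both Ky and the slow component of Kz."""
    Ty = gamma_kernel_support(params.n_y, params.tau_y, tol)
    if params.gamma < 1.0:
        Tz = gamma_kernel_support(params.n_z, params.tau_z, tol)
    else:
        Tz = 0.0
    return max(Ty, Tz)


@dataclass
class KernelPair:
    """Discretized Ky and Kz on offsets 0, dt, 2dt, ... (units 1/ms)."""

    dt: float
    ky: np.ndarray
    kz: np.ndarray
    tail_mass_y: float
    tail_mass_z: float

    @property
    def offsets(self) -> np.ndarray:
        return self.dt * np.arange(len(self.ky))

    @property
    def support(self) -> float:
        return self.dt * (len(self.ky) - 1)

    def center_of_mass(self, which: str = "ky") -> float:
        k = self.ky if which == "ky" else self.kz
        return float(np.sum(self.offsets * k) / np.sum(k))

    def node_time(self) -> float:
        """First positive root of Ky - Kz, with linear sub-grid interpolation.

        In the bright-background limit the flash response is proportional to
        Ky - Kz, so this root is the (background-independent) time of the
        zero crossing between the hyperpolarizing lobe and the overshoot.
        """
        d = self.ky - self.kz
        # skip the initial samples where both kernels are ~0
        start = int(np.argmax(np.abs(d) > 1e-12 * np.max(np.abs(d))))
        sgn = np.sign(d[start:])
        flips = np.nonzero(np.diff(sgn) != 0)[0]
        if len(flips) == 0:
            raise ValueError("Ky - Kz has no sign change on the sampled support")
        i = start + flips[0]
        t0, t1 = self.offsets[i], self.offsets[i + 1]
        d0, d1 = d[i], d[i + 1]
        return float(t0 + (t1 - t0) * d0 / (d0 - d1))


def build_kernels(
    params: ModelParams,
    grid: TimeGrid,
    support: float | None = None,
    tol: float = TAIL_TOL,
) -> KernelPair:
    """Discretize Ky and Kz on the grid's dt.

    The support is extended automatically until the analytic tail mass of
    each component is below ``tol``, then each sampled kernel is
    renormalized so that sum(k) * dt == 1 exactly. An explicitly passed
    ``support`` that truncates more than ``tol`` of the mass raises.
    """
    dt = grid.dt
    if dt > params.tau_y / 4:
        raise ValueError(
            f"dt={dt} ms too coarse to resolve tau_y={params.tau_y} ms (need dt <= tau_y/4)"
        )
    T_needed = kernel_support(params, tol)
    if support is None:
        support = T_needed
    else:
        tail_y = gamma_kernel_tail_mass(support, params.n_y, params.tau_y)
        tail_z = (
            gamma_kernel_tail_mass(support, params.n_z, params.tau_z)
            if params.gamma < 1.0 else 0.0
        )
        if max(tail_y, tail_z) > tol:
            raise ValueError(
                f"kernel support {support} ms truncates tail mass "
                f"{max(tail_y, tail_z):.2e} > {tol:.0e}; need >= {T_needed:.0f} ms"
            )
    m = int(np.ceil(support / dt)) + 1
    t = dt * np.arange(m)

    ky = gamma_kernel(t, params.n_y, params.tau_y)
    tail_y = gamma_kernel_tail_mass(t[-1], params.n_y, params.tau_y)
    ky = ky / (np.sum(ky) * dt)

    if params.gamma < 1.0:
        kslow = gamma_kernel(t, params.n_z, params.tau_z)
        tail_z = gamma_kernel_tail_mass(t[-1], params.n_z, params.tau_z)
        kslow = kslow / (np.sum(kslow) * dt)
    else:
        kslow = np.zeros_like(ky)
        tail_z = 0.0
    kz = params.gamma * ky + (1.0 - params.gamma) * kslow
    kz = kz / (np.sum(kz) * dt)

    return KernelPair(dt=dt, ky=ky, kz=kz, tail_mass_y=tail_y, tail_mass_z=tail_z)


def gamma_kernel_transfer(omega: np.ndarray, n: float, tau: float) -> np.ndarray:
    """Fourier transform of the unit-area gamma kernel: (1 + i w tau)^-(n+1)."""
    return (1.0 + 1j * np.asarray(omega) * tau) ** (-(n + 1.0))


def kernel_transfer(params: ModelParams, omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic transfer functions (Ky_hat, Kz_hat) at angular frequency omega (rad/ms)."""
    ky_hat = gamma_kernel_transfer(omega, params.n_y, params.tau_y)
    kz_hat = (
        params.gamma * ky_hat
        + (1.0 - params.gamma) * gamma_kernel_transfer(omega, params.n_z, params.tau_z)
    )
    return ky_hat, kz_hat
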