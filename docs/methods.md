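# Methods

## The model

`photodyn` simulates and analyzes the dynamical-adaptation (DA) model of
photoreceptor light response. The membrane-potential deflection R(t) (mV,
relative to the dark resting potential; negative under illumination
because vertebrate photoreceptors hyperpolarize to light) obeys the
linear-in-R, feedforward ODE

    tau_r dR/dt = alpha_s * y(t) - (1 + beta * z(t)) * R(t),

where y and z are the light intensity I(t) filtered by two causal,
unit-area kernels,

    y = Ky * I,   z = Kz * I,
    Ky(t) = t^{n_y} e^{-t/tau_y} / (Gamma(n_y+1) tau_y^{n_y+1}),
    Kz(t) = gamma * Ky(t) + (1 - gamma) * Kslow(t),

Kslow being the analogous gamma kernel with (n_z, tau_z). The divisive
term (1 + beta z) sets both the instantaneous gain and the instantaneous
time constant, tau_r / (1 + beta z): gain suppression and response
speed-up co-vary (the gain-bandwidth trade-off). Because Kz is broader
than Ky and delayed, the gain control lags the drive, which is what turns
flash responses biphasic on bright backgrounds, makes adaptation depend
on the input's *history* rather than its instantaneous value, and couples
the mean response to the input's fluctuation statistics.

Being linear in R, the equation has a closed-form solution for any input:

    R(t) = (alpha_s / tau_r) * Int_{-inf}^{t} y(t')
           exp( -(1/tau_r) Int_{t'}^{t} (1 + beta z(s)) ds ) dt'.

All adaptation lives in the accumulated exponent.

### Units and sign conventions

Canonical internal units are milliseconds and photons/um^2/ms; per-second
intensities are converted at the I/O boundary (exact factor 1000).
`alpha` is stored as a positive magnitude (mV um^2 ms/photon) and applied
with the hyperpolarizing sign. `beta` is an inverse intensity,
(photons/um^2/ms)^-1, so that beta*z is dimensionless; with the BHL
parameter set this gives the saturation magnitude alpha/beta =
1.1/0.044 = 25 mV that the flash-family protocol reproduces. The four
packaged parameter sets (salamander cone flicker; turtle-cone data of
Baylor/Hodgkin/Lamb, Burkhardt, Daly/Normann) ship as JSON under
`photodyn/data/`. The salamander set's gain was published in arbitrary
units; the packaged file stores the typical magnitude 2 mV um^2
ms/photon.

## Numerics

* **Kernels** are discretized on the simulation grid, with support
  extended until the analytic tail mass (regularized incomplete gamma)
  falls below 1e-6, then renormalized so the discrete sums times dt are
  exactly one. Non-integer shape exponents use Gamma(n+1). Building
  requires dt <= tau_y/4.
* **Integration** uses an exponential (exact-for-piecewise-constant)
  update with midpoint drives. It is unconditionally stable and lands on
  the quasi-static solution when intense stimuli collapse the effective
  time constant below dt, so arbitrarily bright flashes are integrable;
  only dt > tau_r/2 is rejected. Long traces are processed in
  exponent-renormalized blocks, so the accumulated exponent never
  overflows. Default dt is 0.1 ms for flash/step protocols and 1–2 ms for
  multi-minute flicker runs (chosen for accuracy at the fast end and
  throughput at the slow end; the two regimes differ by the stimulus
  bandwidth, not the model).
* **The exact solution** is evaluated independently by exponentially
  weighted (Duhamel) quadrature of the closed form, with the drive
  piecewise linear within each step; it agrees with the integrator to
  <1e-4 of the peak on flashes, steps, sinusoids and flicker, and is the
  module's standing cross-check.
* **Initial conditions** default to the steady state for the stimulus
  value at the trace start, with the filtering boundary holding the
  initial intensity backwards in time ("the light was on before the
  recording"); a zero-prehistory and a strict (error) policy are
  available.

## Analytic limits

* Small flashes on a background I_B: first-order perturbation gives a
  low-pass (time constant tau_r/(1+beta I_B)) of the pulse
  alpha_s F (Ky - kappa Kz), kappa = beta I_B/(1+beta I_B) — monophasic
  in the dark, converging to the zero-area biphasic pulse Ky - Kz on
  bright backgrounds. Validated against a numerical-derivative oracle
  (<1% mid-range).
* Bright backgrounds: the algebraic (small effective time constant) limit
  R = alpha_s y/(1+beta z); for a flash of ratio phi = F/I_B the response
  is (alpha_s/beta) phi (Ky-Kz)/(1+phi Kz) — a function of the ratio
  alone, with a ratio-independent zero crossing at the root of Ky = Kz.
  The residual O(1/(beta I_B)) corrections are visible for parameter sets
  whose Ky and Kz nearly cancel (BHL), which is why the agreement bound
  in the tests is stated at beta I_B = 200.
* Weber-Fechner: the step sensitivity (peak incremental response per unit
  probe, probe small against both I_B and 1/beta) normalized to its dark
  value follows (1 + I_B/I_0)^-1 over seven decades with bright-end
  log-log slope -1.
* Sinusoids: at small contrast the response follows the linearized
  transfer function alpha_s (Ky^ - kappa Kz^)/((1+beta I_B)(1 + i w
  tau_r/(1+beta I_B))) (gamma-kernel transforms are (1+i w tau)^-(n+1)),
  a band-pass on bright backgrounds because the unit-area kernels cancel
  at w -> 0; at full contrast the response rides the saturating
  nonlinearity and stays low-pass.

## Gaussian-flicker statistics

For I(t) = I_B (1 + sigma(t) xi(t)) with xi a unit-variance Gaussian
process of correlation C (exponential, or the frame-hold process of CRT
experiments), the mean response over flicker instantiations is computed
two ways:

1. **Gaussian average of the exact solution.** Both y-fluctuations and
   the accumulated exponent are jointly Gaussian, so the average is
   closed-form: the drive acquires a -Cov(y_f, B) correction and the
   exponent a +Var(B)/2 boost, with B the accumulated gain-control
   fluctuation. The stationary engine reduces this to 1-D lag quadrature
   over kernel-correlation functions; the enveloped engine builds the
   full covariance matrices on the grid (O(N^2) memory, fft-based) and
   handles variance switching, flashes at arbitrary phases, and the
   frame-hold correlation structure exactly. The lognormal e^{Var/2}
   factor is kept in full where the deterministic decay dominates the
   variance growth; otherwise (strong, long-correlated flicker, where the
   unclipped-Gaussian mean genuinely diverges) the engine falls back to
   the second-order truncation.
2. **Bright-limit overlap forms.** To lowest order in sigma, with
   Omega_ab = Int Int Ka(u) Kb(v) C(u-v): the tonic response is scaled by
   1 - kappa sigma^2 Omega_yz + kappa^2 sigma^2 Omega_zz, the mean flash
   response is boosted by 1 + kappa^2 sigma^2 Omega_zz (always >= 1: a
   gain enhancement), and acquires a Kz-shaped additive term proportional
   to 2 kappa^2 sigma^2 (kappa Omega_zz - Omega_yz). Long-correlation
   flicker drives both overlaps to 1, so the tonic mean is then always
   depolarized relative to mean-matched constant light; short-correlation
   flicker with a strongly delayed Kz flips the sign.

Every closed form is validated against seeded Monte-Carlo simulation
(500 instantiations per condition, 2-SEM agreement at contrasts up to
35% and correlation times of 20 and 200 ms). The Monte-Carlo comparisons
use unclipped Gaussian draws, because that is the process the formulas
average over; the physical generator clips at zero intensity, which at
35% contrast affects 0.2% of samples and shifts the tonic mean by about
0.1% — negligible at the tested precision but documented here.

The variance-switch protocol (s.d. alternating 35%/5% with a 1-s period)
uses a background of 150 photons/um^2/ms; the published protocol's mean
intensity was not recoverable, and this value puts the model deep enough
into the divisive regime (beta I_B = 10) that the switch response is
resolvable in a few hundred Monte-Carlo replicates. At each s.d.
step-up the mean response transiently depolarizes — the averaged trace
peaks within ~300 ms of the switch and relaxes back — and at each
step-down it transiently hyperpolarizes (the delayed Kz again). For this
parameter set the step-down undershoot is an order of magnitude smaller
than the step-up transient; its sign is established by the analytic
engine, while Monte-Carlo at practical replicate counts resolves only
the step-up transient and the half-period level shift.

## LN baseline and gain diagnostics

The LN filter is ridge-regularized least squares on the lagged stimulus
matrix (ridge chosen by GCV; ridge=0 recovers plain cross-correlation,
adequate for white inputs), followed by an OLS degree-3 polynomial from
linear prediction to response. Instantaneous gain is the OLS slope of
response against linear prediction over +-150 ms flanking windows,
summarized in 300-ms windows every 100 ms and paired with the mean
intensity over the preceding 300 ms. Gains are split into ten percentile
groups; each group's averaged, zero-padded window cross-correlation
provides a group filter and (with parabolic sub-grid refinement, since
group timing differences are of order milliseconds) a peak-correlation
lag. Significance uses a circular-shift Monte-Carlo: the statistic is
recomputed under random circular rotations of the stimulus (excluding
shifts within the filter length of zero) and the two-sided p-value is
add-one corrected, (1 + #{|shuffled| >= |observed|})/(1 + n). On
DA-generated flicker the diagnostics reproduce the expected signatures:
gain anticorrelates with recent intensity, dim-history corrective gain
exceeds bright-history gain under linear or LN predictions but not under
the DA model's own prediction, and filter amplitude and latency grow
with the gain percentile.

## Fitting

Q = 1 - SSE / sum(n_t var_t) over matched trace sets (count-weighted
variances; zero-variance observations are rejected rather than silently
absorbed). Parameters are optimized in log coordinates with bounded
trust-region least squares and finite-difference gradients; optional
multi-start, integer-shape pinning (continuous fit, round n_y/n_z,
re-polish), and per-trace closed-form gain rescaling. The identifiable
quantities are alpha, beta, gamma, tau_r, and the products n_y tau_y and
n_z tau_z — within a kernel, shape and time constant trade off along
shallow valleys of Q, which the sensitivity module exposes via 1-D Q
profiles and the numerically estimated Hessian at the optimum (with a
direct grid fallback when a block is indefinite). Synthetic-recovery
tests (20 seeded flicker datasets, 1% noise, +-30% perturbed inits)
recover all identifiable quantities with median error well under 10%.

## The naturalistic surrogate

`make_naturalistic_surrogate` exponentiates the sum of two
Ornstein-Uhlenbeck processes (correlation times 30 ms and 1.5 s,
log-s.d. 1.05 each) and rescales to a target mean. It emulates exactly
two properties of natural intensity series — a 1st-99th percentile range
close to three decades, and variation on scales from tens of
milliseconds to seconds — and nothing finer: no 1/f spectrum, no
occlusion/saccade structure, no spatial correlates. Tests passing on it
show that the model's fast gain modulation (probe responses spreading
>5-fold, mean probe response exceeding the mean-matched constant-
background response) follows from those two properties alone; they do
not certify behavior on real radiometric recordings.

## Problem sizes

Default protocol sizes were chosen to make every documented effect
well-resolved at comfortable numerical margins: flash/step protocols run
at dt = 0.1 ms over 1.5–3 s; flicker Monte-Carlo uses 500 instantiations
of 3–5 s traces at dt = 1–2 ms; the LN diagnostics use a 200-s flicker
recording at dt = 5 ms (the slope-difference shuffle test needs traces of
this length for its significance level); parameter recovery uses 10-s
traces. The acceptance script runs in a few seconds; the full test suite
in a few minutes.

## Known limitations

* The compressive flash-pair protocol reproduces strong (far
  sub-proportional) peak compression on bright backgrounds, but the
  specific 5:1 ratio for a 400-fold flash pair depends on a stimulus
  contrast that is one free parameter of the protocol; see the test
  suite for the a-priori reconstruction used.
* No long-term (seconds-to-minutes) adaptation, no photon shot noise or
  transduction noise, no spatial structure.
* The non-monotonic slow-down of flash responses under extremely bright
  backgrounds seen in some recordings is outside the model class.
* The flicker closed forms are perturbative in the flicker s.d. (the
  lognormal resummation is exact for the unclipped process where it
  converges); at contrasts well above 35%, or for strongly clipped
  regimes, only the Monte-Carlo route is reliable.
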