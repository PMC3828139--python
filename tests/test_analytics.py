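"""Closed-form limits, Weber/frequency curves, and flicker statistics,
each checked against an independent simulator or quadrature oracle."""
import numpy as np
import pytest

from photodyn import (
    FlickerSpec,
    TimeGrid,
    bright_limit_flash_response,
    build_kernels,
    constant_stimulus,
    fit_weber_law,
    flash_on_background,
    flicker_flash_modulation,
    flicker_mean_response,
    frequency_gain_curve,
    kernel_overlaps,
    linearized_gain,
    mean_response_second_order,
    simulate_da,
    small_flash_response,
    stationary_tonic_mean,
    steady_state_response,
    weber_sensitivity_curve,
)
from photodyn.analytics import _flicker_grid, flicker_additive_pulse, flicker_gain_boost
from photodyn.stimuli import PulseEvent, PulseProtocol, make_pulse_stimulus


class TestSmallFlash:
    def test_dark_response_monophasic(self, paramsets):
        p = paramsets["b"]
        grid = TimeGrid.from_duration(1500, 0.5)
        r = small_flash_response(0.0, 1.0, p, grid).response
        assert np.all(r <= 1e-12 * np.max(np.abs(r)))

    def test_bright_response_integrates_to_zero(self, paramsets):
        p = paramsets["b"]
        grid = TimeGrid.from_duration(2000, 0.5)
        dim = small_flash_response(0.0, 1.0, p, grid).response
        bright = small_flash_response(1e4, 1.0, p, grid).response
        frac = lambda r: abs(np.trapezoid(r, dx=0.5)) / np.trapezoid(np.abs(r), dx=0.5)
        assert frac(bright) < 0.02
        assert frac(dim) > 0.9

    def test_amplitude_proportional_to_flash(self, paramsets):
        p = paramsets["dn"]
        grid = TimeGrid.from_duration(1000, 0.5)
        r1 = small_flash_response(10.0, 1.0, p, grid).response
        r3 = small_flash_response(10.0, 3.0, p, grid).response
        np.testing.assert_allclose(r3, 3.0 * r1, rtol=1e-12)

    def test_matches_numerical_derivative(self, paramsets):
        """First-order theory vs (simulate(bg+flash) - simulate(bg))/F as
        F -> 0, at a mid-range background: relative error < 1%."""
        p = paramsets["b"]
        I_B = 5.0
        grid = TimeGrid.from_duration(1200, 0.5)
        an = small_flash_response(I_B, 1.0, p, grid).response
        g2 = TimeGrid.from_duration(1400, 0.5, t0=-200)
        eps = 1e-4 * (I_B + 1.0 / p.beta)
        st = flash_on_background(I_B, eps, g2, onset=0.0, duration=0.5)
        num = (simulate_da(st, p).response
               - simulate_da(constant_stimulus(I_B, g2), p).response) / eps
        sel = g2.times >= 0
        gap = np.max(np.abs(an - num[sel][: grid.n]))
        assert gap < 0.01 * np.max(np.abs(an))


class TestBrightLimit:
    def test_node_time_invariance(self, paramsets):
        """The biphasic response's zero crossing solves Ky = Kz and does not
        move with the flash/background ratio (within one grid step)."""
        p = paramsets["b"]
        grid = TimeGrid(0.0, 0.1, 12001)
        node = build_kernels(p, grid).node_time()
        for phi in (0.1, 1.0, 10.0):
            d = bright_limit_flash_response(phi, p, grid).response
            i0 = int(np.argmin(d))
            cross = np.nonzero((d[i0:-1] < 0) & (d[i0 + 1:] >= 0))[0]
            t_node = grid.times[i0 + cross[0]]
            assert abs(t_node - node) <= grid.dt

    def test_full_model_agreement_improves_with_background(self, paramsets):
        p = paramsets["dn"]
        gaps = []
        for b in (20.0, 200.0):
            I_B = b / p.beta
            g = TimeGrid.from_duration(1400, 0.2, t0=-200)
            st = flash_on_background(I_B, 1.0 * I_B, g, onset=0.0, duration=0.2)
            sim = (simulate_da(st, p).response
                   - simulate_da(constant_stimulus(I_B, g), p).response)
            sel = g.times >= 0
            an = bright_limit_flash_response(
                1.0, p, TimeGrid(0.0, 0.2, int(sel.sum()))).response
            gaps.append(np.max(np.abs(an - sim[sel])) / np.max(np.abs(sim)))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 0.03

    def test_saturated_profile_fixed(self, paramsets):
        """As the flash/background ratio grows the normalized early-time
        profile converges (saturation of the response shape)."""
        p = paramsets["b"]
        grid = TimeGrid(0.0, 0.5, 2000)
        a = bright_limit_flash_response(1e4, p, grid).response
        b = bright_limit_flash_response(1e5, p, grid).response
        sel = (grid.times > 20) & (grid.times < 80)
        np.testing.assert_allclose(a[sel] / np.min(a), b[sel] / np.min(b), rtol=0.05)


class TestWeber:
    def test_weber_fechner_over_seven_decades(self, paramsets):
        p = paramsets["b"]
        bgs = np.geomspace(1e-3, 1e4, 22)
        sens = weber_sensitivity_curve(p, bgs)
        assert sens[0] <= 1.0 + 1e-6
        assert np.all(np.diff(sens) < 0)
        fit = fit_weber_law(bgs, sens)
        assert fit["r_squared"] > 0.98
        assert fit["bright_slope"] == pytest.approx(-1.0, abs=0.05)


class TestFrequencyGain:
    def test_band_pass_at_low_contrast(self, paramsets):
        p = paramsets["b"]
        g = frequency_gain_curve(360.0, 0.01, [0.05, 2.5], p, dt=2.0)
        assert g[0] < 0.5 * g[1]

    def test_low_pass_at_full_contrast(self, paramsets):
        p = paramsets["b"]
        freqs = [0.1, 1.25, 2.5, 5.0]
        g = frequency_gain_curve(360.0, 1.0, freqs, p, dt=2.0)
        assert g[0] >= 0.5 * np.max(g)

    def test_linearized_transfer_oracle(self, paramsets):
        """At 1% contrast the simulated gain matches the closed-form
        linearized transfer function within 2%."""
        p = paramsets["b"]
        freqs = [0.1, 1.25, 5.0]
        sim = frequency_gain_curve(360.0, 0.01, freqs, p, dt=1.0)
        lin = linearized_gain(360.0, freqs, p)
        np.testing.assert_allclose(sim, lin, rtol=0.02)


class TestOverlaps:
    def test_infinite_correlation_gives_unity(self, paramsets):
        k = build_kernels(paramsets["b"], TimeGrid(0.0, 1.0, 2))
        ov = kernel_overlaps(k, lambda lag: np.ones_like(np.asarray(lag, float)))
        for v in ov.values():
            assert v == pytest.approx(1.0, abs=1e-4)

    def test_monotone_in_correlation_time(self, paramsets):
        k = build_kernels(paramsets["b"], TimeGrid(0.0, 1.0, 2))
        taus = [10.0, 50.0, 250.0, 1250.0]
        vals = [kernel_overlaps(k, lambda lag, t=t: np.exp(-np.abs(lag) / t))["yz"]
                for t in taus]
        assert np.all(np.diff(vals) > 0)

    def test_dense_quadrature_oracle(self, paramsets):
        """Direct O(K^2) double sum agrees with the correlation-based path."""
        p = paramsets["dn"]
        k = build_kernels(p, TimeGrid(0.0, 2.0, 2))
        tau_c = 30.0
        C = lambda lag: np.exp(-np.abs(lag) / tau_c)
        fast = kernel_overlaps(k, C)["yz"]
        t = k.offsets
        direct = float(np.sum(
            k.ky[:, None] * k.kz[None, :] * C(t[:, None] - t[None, :])
        ) * k.dt * k.dt)
        assert fast == pytest.approx(direct, rel=1e-6)


class TestFlickerStats:
    def test_zero_variance_reductions(self, paramsets):
        p = paramsets["b"]
        spec = FlickerSpec(mean=30.0, sigma=0.0, correlation="exponential",
                           tau_c_ms=200.0)
        stats = flicker_flash_modulation(spec, 50.0, p, window=400.0, dt=2.0)
        assert stats.boost == pytest.approx(1.0)
        np.testing.assert_allclose(stats.additive, 0.0, atol=1e-12)
        assert stats.tonic_mean == pytest.approx(
            steady_state_response(30.0, p), rel=2e-3)
        tonic = flicker_mean_response(spec, p)
        assert tonic.tonic_mean == pytest.approx(
            steady_state_response(30.0, p), rel=2e-4)

    def test_boost_exceeds_one_and_tracks_correlation_time(self, paramsets):
        p = paramsets["b"]
        boosts = {}
        for tc in (20.0, 2000.0):
            spec = FlickerSpec(mean=30.0, sigma=0.35, correlation="exponential",
                               tau_c_ms=tc)
            k = build_kernels(p, TimeGrid(0.0, 1.0, 2))
            ov = kernel_overlaps(k, lambda lag, t=tc: np.exp(-np.abs(lag) / t))
            boosts[tc] = flicker_gain_boost(p, 30.0, 0.35, ov)
        assert all(b > 1.0 for b in boosts.values())
        assert boosts[2000.0] > boosts[20.0]

    def test_stationary_engine_consistency(self, paramsets):
        """The 1-D stationary quadrature and the covariance-matrix engine
        give the same tonic mean."""
        p = paramsets["b"]
        spec = FlickerSpec(mean=30.0, sigma=0.35, correlation="exponential",
                           tau_c_ms=200.0)
        tonic = stationary_tonic_mean(p, spec)
        grid, _ = _flicker_grid(p, spec, 1500.0, 1.0)
        trace = mean_response_second_order(p, spec, grid)
        tail = np.mean(trace.response[grid.times > 700])
        assert tail == pytest.approx(tonic, abs=0.06)

    def test_long_correlation_flicker_depolarizes_mean(self, paramsets):
        """For long-correlation flicker both overlaps approach one, so the
        mean response under flicker is depolarized (smaller magnitude)
        relative to mean-matched constant light."""
        p = paramsets["b"]
        spec = FlickerSpec(mean=30.0, sigma=0.35, correlation="exponential",
                           tau_c_ms=500.0)
        tonic = stationary_tonic_mean(p, spec)
        assert abs(tonic) < abs(steady_state_response(30.0, p))

    def test_short_correlation_delayed_kz_hyperpolarizes_mean(self, paramsets):
        """Bright background + strongly delayed Kz + short-correlation
        flicker: the cross-overlap collapses while the self-overlap term
        survives, and the mean response is enhanced (more hyperpolarized)."""
        p = paramsets["b"].replace(gamma=0.02, n_z=12.0, tau_z=40.0)
        spec = FlickerSpec(mean=3000.0, sigma=0.35, correlation="exponential",
                           tau_c_ms=3.0)
        tonic = stationary_tonic_mean(p, spec, dt=0.5)
        assert abs(tonic) > abs(steady_state_response(3000.0, p))

    def test_variance_switch_transient_signs(self, paramsets):
        """At a variance step-up the mean response transiently depolarizes
        beyond its new quasi-steady level; at a step-down it transiently
        hyperpolarizes."""
        from photodyn import square_wave_envelope

        p = paramsets["b"]
        env = square_wave_envelope(1000.0, low=0.05, high=0.35)
        spec = FlickerSpec(mean=500.0, sigma=0.35, correlation="hold",
                           hold_ms=30.0, envelope=env)
        grid = TimeGrid.from_duration(4000, 2.0, t0=-1000)
        tr = mean_response_second_order(p, spec, grid)
        t, r = tr.times, tr.response
        hi = r[(t >= 1300) & (t < 1450)].mean()
        lo = r[(t >= 1800) & (t < 1950)].mean()
        assert r[(t >= 1000) & (t < 1250)].max() > hi + 1e-3
        assert r[(t >= 1500) & (t < 1750)].min() < lo - 1e-3


class TestAsymmetry:
    def test_dark_flash_deflects_more_than_bright(self, paramsets):
        """On a light background, a dark flash produces a larger-magnitude
        peak deflection than an equally strong bright flash."""
        p = paramsets["b"]
        I_B = 260.0
        grid = TimeGrid.from_duration(3000, 0.5, t0=-500)
        base = simulate_da(constant_stimulus(I_B, grid), p).response
        up = make_pulse_stimulus(PulseProtocol(I_B, (
            PulseEvent(0.0, I_B * 100, 100.0, "flash"),)), grid)
        dn = make_pulse_stimulus(PulseProtocol(I_B, (
            PulseEvent(0.0, -I_B * 100, 100.0, "flash"),)), grid)
        d_up = simulate_da(up, p).response - base
        d_dn = simulate_da(dn, p).response - base
        assert np.max(np.abs(d_dn)) > np.max(np.abs(d_up))
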