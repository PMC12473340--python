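"""Pulse math, super-Lorentzian lineshape and the two-pool forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmtkit.mt_physics import (
    OFFSET_FLOOR_HZ,
    OnResonanceError,
    RFPulse,
    TwoPoolParams,
    UnsupportedPulseShapeError,
    flip_to_peak_omega1,
    omega1_cwpe,
    omega1_rms,
    pulse_envelope,
    ramani_signal,
    ramani_signal_arrays,
    rrfb,
    super_lorentzian_g,
)


def _make_pulse(flip=500.0, dur=10.24e-3, bw=200.0, off=1e3, tr=0.05):
    return RFPulse(flip_angle_deg=flip, duration_s=dur, bandwidth_hz=bw, offset_hz=off, tr_s=tr)


class TestEnvelope:
    def test_sigma_from_bandwidth(self):
        # Gaussian Fourier pair: 200 Hz spectral FWHM -> 1.874 ms temporal sigma
        sigma_expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) / (2.0 * math.pi * 200.0)
        assert _make_pulse().sigma_t == pytest.approx(sigma_expected, rel=1e-12)
        assert _make_pulse().sigma_t == pytest.approx(1.874e-3, rel=1e-3)

    def test_center_equals_peak_and_truncation(self):
        p = _make_pulse()
        env = pulse_envelope(p, peak_rate=123.0)
        assert env(p.duration_s / 2.0) == pytest.approx(123.0)
        assert env(-1e-6) == 0.0
        assert env(p.duration_s + 1e-6) == 0.0

    def test_unsupported_shape(self):
        p = _make_pulse()
        object.__setattr__(p, "shape", "sinc")
        with pytest.raises(UnsupportedPulseShapeError):
            pulse_envelope(p, 1.0)
        with pytest.raises(UnsupportedPulseShapeError):
            flip_to_peak_omega1(p)

    def test_flip_angle_round_trip_against_quadrature(self):
        # the envelope integral (calibrated analytically) must reproduce the
        # requested flip angle under an independent trapezoid-rule quadrature
        p = _make_pulse()
        peak = flip_to_peak_omega1(p)
        t = np.linspace(0.0, p.duration_s, 100_001)
        flip_quad = np.degrees(np.trapezoid(pulse_envelope(p, peak)(t), t))
        assert flip_quad == pytest.approx(p.flip_angle_deg, rel=1e-8)

    def test_peak_rate_linear_in_flip(self):
        assert flip_to_peak_omega1(_make_pulse(flip=700.0)) == pytest.approx(
            2.0 * flip_to_peak_omega1(_make_pulse(flip=350.0)), rel=1e-12
        )

    def test_rectangular_limit(self):
        # a very wide spectral FWHM relative to 1/duration makes the envelope
        # nearly flat, so peak omega1 -> theta_rad / t_mt
        p = _make_pulse(flip=500.0, bw=0.5)
        theta = math.radians(500.0)
        assert flip_to_peak_omega1(p) == pytest.approx(theta / p.duration_s, rel=1e-3)


class TestCwEquivalents:
    def test_power_identity(self, protocol_pulses):
        # both conventions integrate the same power, with different normalizers
        for p in protocol_pulses:
            assert omega1_cwpe(p) ** 2 * p.tr_s == pytest.approx(
                omega1_rms(p) ** 2 * p.duration_s, rel=1e-12
            )

    def test_rms_at_least_cwpe(self, protocol_pulses):
        for p in protocol_pulses:
            assert omega1_rms(p) >= omega1_cwpe(p)

    def test_flat_pulse_closed_forms(self):
        # near-flat envelope with duty cycle d: cwpe -> peak*sqrt(d), rms -> peak
        p = _make_pulse(bw=0.5)
        peak = flip_to_peak_omega1(p)
        duty = p.duration_s / p.tr_s
        assert omega1_rms(p) == pytest.approx(peak, rel=1e-3)
        assert omega1_cwpe(p) == pytest.approx(peak * math.sqrt(duty), rel=1e-3)

    def test_rms_linear_in_flip(self):
        r = omega1_rms(_make_pulse(flip=500.0)) / omega1_rms(_make_pulse(flip=350.0))
        assert r == pytest.approx(500.0 / 350.0, rel=1e-12)

    def test_single_offset_pulse_against_quadrature_oracle(self, single_offset_pulse):
        # independent trapezoid-rule oracle for int omega1^2 dt at 1e5 samples
        p = single_offset_pulse
        sigma = 2.0 * math.sqrt(2.0 * math.log(2.0)) / (2.0 * math.pi * p.bandwidth_hz)
        t = np.linspace(0.0, p.duration_s, 100_001)
        env = np.exp(-((t - p.duration_s / 2.0) ** 2) / (2.0 * sigma**2))
        peak = math.radians(p.flip_angle_deg) / np.trapezoid(env, t)
        w_cwpe_oracle = math.sqrt(np.trapezoid((peak * env) ** 2, t) / p.tr_s)
        assert omega1_cwpe(p) == pytest.approx(w_cwpe_oracle, rel=1e-8)
        assert omega1_cwpe(p) > 0


class TestSuperLorentzian:
    def test_monotone_tail(self):
        offs = np.array([1e3, 2e3, 5e3, 10e3, 50e3, 100e3])
        g = super_lorentzian_g(offs, 6e-6)
        assert np.all(np.diff(g) < 0)
        assert np.all(g > 0)

    def test_quadrature_self_convergence(self):
        g1 = super_lorentzian_g(1e3, 6e-6, order=512)
        g4 = super_lorentzian_g(1e3, 6e-6, order=2048)
        assert abs(g1 - g4) / g4 < 1e-6

    def test_scaling_relation(self):
        # G(df, T2B) = T2B * Ghat(df * T2B): equal products, G ratio = T2B ratio
        g_a = super_lorentzian_g(2e3, 6e-6)
        g_b = super_lorentzian_g(1e3, 12e-6)
        assert g_a / g_b == pytest.approx(0.5, rel=1e-10)

    def test_on_resonance_floor(self):
        with pytest.raises(OnResonanceError):
            super_lorentzian_g(OFFSET_FLOOR_HZ / 2.0, 6e-6)


class TestRrfb:
    def test_quadratic_in_omega1(self):
        assert rrfb(200.0, 1e3, 6e-6) == pytest.approx(4.0 * rrfb(100.0, 1e3, 6e-6), rel=1e-12)

    def test_zero_amplitude(self):
        assert rrfb(0.0, 1e3, 6e-6) == 0.0

    def test_far_offset_negligible(self):
        assert rrfb(400.0, 100e3, 6e-6) / rrfb(400.0, 1e3, 6e-6) < 1e-3


class TestTwoPoolSignal:
    def test_far_offset_near_unity(self, muscle_params):
        p = _make_pulse(flip=650.0, off=100e3)
        sn = ramani_signal(muscle_params, p)
        assert abs(sn - 1.0) < 0.005

    def test_no_bound_pool_reduces_to_direct_saturation(self, mt_pulse):
        # F = 0 leaves only the direct free-pool saturation term
        params = TwoPoolParams(F=0.0, rm0a=48.0, RA=0.7, T2A=0.035, T2B=6e-6)
        sn = ramani_signal(params, mt_pulse)
        w1 = omega1_cwpe(mt_pulse)
        r_rfb = rrfb(w1, mt_pulse.offset_hz, 6e-6)
        direct = (w1 / (2 * math.pi * mt_pulse.offset_hz)) ** 2 / (0.7 * 0.035)
        rb = 1.0
        expected = (rb + r_rfb + 48.0) / ((1 + direct) * (r_rfb + rb + 48.0))
        assert sn == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_F(self, mt_pulse):
        f_grid = np.linspace(0.0, 0.3, 31)
        sn = ramani_signal_arrays(f_grid, 48.0, 0.7, 1.0, 0.035, 6e-6, omega1_cwpe(mt_pulse), 1e3)
        assert np.all(np.diff(sn) < 0)

    def test_ramani_at_least_yarnykh(self, muscle_params, protocol_pulses):
        for p in protocol_pulses:
            assert ramani_signal(muscle_params, p, "ramani") >= ramani_signal(
                muscle_params, p, "yarnykh"
            )

    def test_validation_errors(self, muscle_params):
        with pytest.raises(ValueError):
            ramani_signal(muscle_params, _make_pulse(off=10.0))
        bad = TwoPoolParams(F=0.07, rm0a=48.0, RA=0.7, T2A=0.035, T2B=6e-6)
        object.__setattr__(bad, "RA", float("nan"))
        with pytest.raises(ValueError):
            ramani_signal(bad, _make_pulse())

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        F=st.floats(0.0, 0.4),
        rm0a=st.floats(5.0, 150.0),
        ra=st.floats(0.3, 2.0),
        t2a=st.floats(0.01, 0.15),
        t2b_us=st.floats(2.0, 25.0),
        flip=st.floats(100.0, 900.0),
        off_khz=st.floats(1.0, 100.0),
        mode=st.sampled_from(["ramani", "yarnykh"]),
    )
    def test_signal_in_unit_interval(self, F, rm0a, ra, t2a, t2b_us, flip, off_khz, mode):
        """Sn stays in (0, 1] over the whole physical parameter space."""
        params = TwoPoolParams(F=F, rm0a=rm0a, RA=ra, T2A=t2a, T2B=t2b_us * 1e-6)
        p = _make_pulse(flip=flip, off=off_khz * 1e3)
        sn = ramani_signal(params, p, mode)
        assert 0.0 < sn <= 1.0


def test_signal_unit_interval_random_grid(rng):
    """Dense vectorized sweep of the physical parameter box (10^4 points)."""
    n = 10_000
    F = rng.uniform(0.0, 0.4, n)
    rm0a = rng.uniform(5.0, 150.0, n)
    ra = rng.uniform(0.3, 2.0, n)
    t2a = rng.uniform(0.01, 0.15, n)
    t2b = rng.uniform(2e-6, 25e-6, n)
    off = rng.uniform(1e3, 100e3, n)
    w1 = rng.uniform(10.0, 1500.0, n)
    sn = np.array(
        [
            ramani_signal_arrays(F[i], rm0a[i], ra[i], 1.0, t2a[i], t2b[i], w1[i], off[i])
            for i in range(n)
        ]
    )
    assert np.all(sn > 0.0) and np.all(sn <= 1.0)
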