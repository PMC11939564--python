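"""Preprocessing chain oracles: demodulation, zero-phase filtering,
resampling, detrending, derivative channels, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarbp.config import PrepConfig, SimConfig
from radarbp.preprocess import (Signal, bandpass, bandpass_gain, demodulate,
                                detrend, l2_normalize, nth_derivative,
                                preprocess_record, resample_to)
from radarbp.simulate import simulate_subject


class TestDemodulate:
    def test_constant_iq_gives_zero_displacement(self):
        n = 100
        d = demodulate(Signal(np.ones(n), 100.0),
                       Signal(np.zeros(n), 100.0), 0.01)
        assert np.allclose(d.samples, 0.0)

    def test_linear_phase_ramp(self):
        """phi(t) = 2*pi*t with lambda = 0.01 m inverts to displacement of
        slope 2*pi*0.01/(4*pi) = 0.005 m/s."""
        fs, lam = 1000.0, 0.01
        t = np.arange(0, 2, 1 / fs)
        phi = 2 * np.pi * t
        d = demodulate(Signal(np.cos(phi), fs), Signal(np.sin(phi), fs), lam)
        slope_mm = np.polyfit(t, d.samples, 1)[0]
        assert slope_mm / 1000.0 == pytest.approx(0.005, rel=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            demodulate(Signal(np.zeros(10), 10.0),
                       Signal(np.zeros(10), 10.0), 0.01)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            demodulate(Signal(np.ones(10), 10.0),
                       Signal(np.zeros(9), 10.0), 0.01)


class TestBandpass:
    def test_passband_sinusoid_amplitude_and_lag(self):
        """5 Hz sits inside the band: amplitude within 2% of the analytic
        |H|^2 response and zero cross-correlation lag (zero-phase)."""
        fs = 150.0
        cfg = PrepConfig()
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 5 * t)
        y = bandpass(Signal(x, fs), cfg).samples
        core = slice(1500, -1500)
        gain = np.abs(y[core]).max()
        assert gain == pytest.approx(bandpass_gain(cfg, fs, 5.0), rel=0.02)
        xc = np.correlate(x[core], y[core], "full")
        lag = np.argmax(xc) - (len(x[core]) - 1)
        assert lag == 0

    def test_respiration_band_attenuated(self):
        cfg = PrepConfig()
        assert 10 * np.log10(bandpass_gain(cfg, 2000.0, 0.05)) < -20.0

    def test_zero_input_zero_output(self):
        y = bandpass(Signal(np.zeros(1000), 150.0), PrepConfig())
        assert np.allclose(y.samples, 0.0)

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass(Signal(np.zeros(1000), 20.0), PrepConfig())


class TestResample:
    def test_length_arithmetic_2000_to_150(self):
        y = resample_to(Signal(np.zeros(20000), 2000.0), 150.0)
        assert y.samples.size == 1500
        assert y.fs == 150.0

    def test_sinusoid_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(0, 10, 1 / fs)
        y = resample_to(Signal(np.sin(2 * np.pi * 1.0 * t), fs), 150.0)
        assert np.abs(y.samples[100:-100]).max() == pytest.approx(1.0,
                                                                  rel=0.02)

    def test_dc_preserved(self):
        y = resample_to(Signal(np.full(4000, 3.7), 2000.0), 150.0)
        assert np.allclose(y.samples[10:-10], 3.7, atol=1e-6)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to(Signal(np.zeros(100), 100.0), 200.0)


class TestDetrend:
    def test_constant_series(self):
        out, tm = detrend(Signal([5.0, 5, 5, 5], 1.0))
        assert np.allclose(out.samples, 0.0)
        assert tm.alpha0 == pytest.approx(5.0)
        assert tm.alpha1 == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        out, tm = detrend(Signal([1.0, 2, 3, 4], 1.0))
        assert np.allclose(out.samples, 0.0, atol=1e-12)
        assert tm.alpha1 == pytest.approx(1.0)

    def test_closed_form_ols(self):
        """[1,3,2,5] on index 0..3: slope 1.1, intercept 1.1, residuals
        [-0.1, 0.8, -1.3, 0.6] (hand-computed least squares)."""
        out, tm = detrend(Signal([1.0, 3, 2, 5], 1.0))
        assert tm.alpha1 == pytest.approx(1.1, abs=1e-10)
        assert tm.alpha0 == pytest.approx(1.1, abs=1e-10)
        assert np.allclose(out.samples, [-0.1, 0.8, -1.3, 0.6], atol=1e-10)

    def test_residual_moments(self):
        rng = np.random.default_rng(0)
        x = Signal(rng.normal(size=500) + np.linspace(0, 3, 500), 10.0)
        out, _ = detrend(x)
        n = out.samples.size
        assert abs(out.samples.mean()) < 1e-9 * np.abs(x.samples).max()
        assert abs(np.corrcoef(out.samples, np.arange(n))[0, 1]) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = Signal(rng.normal(size=64), 10.0)
        once, _ = detrend(x)
        twice, _ = detrend(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-9)


class TestDerivative:
    def test_second_derivative_exact_on_quadratic(self):
        y = Signal(np.arange(30.0) ** 2, 1.0)
        d = nth_derivative(y, 2)
        assert np.allclose(d.samples[1:-1], 2.0)

    def test_linear_series_zero(self):
        d = nth_derivative(Signal(np.arange(30.0), 1.0), 2)
        assert np.allclose(d.samples[1:-1], 0.0)

    def test_sampling_period_scaling(self):
        y = Signal((np.arange(30.0) * 0.1) ** 2, 10.0)  # y = t^2 at Ts=0.1
        d = nth_derivative(y, 2)
        assert np.allclose(d.samples[1:-1], 2.0)
        # in index units: y[n] = n^2 with Ts = 0.1 -> 2/0.01 = 200
        d2 = nth_derivative(Signal(np.arange(30.0) ** 2, 10.0), 2)
        assert np.allclose(d2.samples[1:-1], 200.0)

    def test_order1_twice_matches_order2_up_to_alignment(self):
        """Two first-difference passes reproduce the centred second
        difference on interior samples, shifted by the known one-sample
        alignment of one-sided differencing."""
        x = Signal(np.sin(np.arange(100) * 0.1), 1.0)
        dd = nth_derivative(nth_derivative(x, 1), 1).samples
        d2 = nth_derivative(x, 2).samples
        assert np.allclose(d2[2:-2], dd[1:-3], atol=1e-9)

    def test_output_length_preserved(self):
        for order in (1, 2, 3):
            d = nth_derivative(Signal(np.arange(20.0) ** 3, 1.0), order)
            assert d.samples.size == 20

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            nth_derivative(Signal([1.0, 2.0], 1.0), 3)


class TestNormalize:
    def test_three_four_five(self):
        assert np.allclose(l2_normalize([3.0, 4.0]), [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        v = np.array([0.6, 0.8])
        assert np.allclose(l2_normalize(v), v)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40))
    def test_unit_norm_contract(self, values):
        x = np.asarray(values)
        if np.linalg.norm(x) < 1e-9:
            return
        assert np.linalg.norm(l2_normalize(x)) == pytest.approx(1.0,
                                                                abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            l2_normalize(np.zeros(5))


def test_record_chain_recovers_cardiac_band():
    """demodulate -> bandpass -> resample keeps the cardiac pulse train:
    the RCMV correlates with the band-passed true displacement."""
    cfg = SimConfig(duration_s=30.0, seed=4, noise_sd=0.0)
    rec = simulate_subject(cfg)
    pc = PrepConfig(guard_s=0.0)
    rcmv = preprocess_record(Signal(rec.radar_i, rec.radar_fs),
                             Signal(rec.radar_q, rec.radar_fs),
                             cfg.wavelength, pc)
    assert rcmv.fs == 150.0
    ref = resample_to(bandpass(Signal(rec.displacement_mm, rec.radar_fs),
                               pc), 150.0)
    r = np.corrcoef(rcmv.samples, ref.samples)[0, 1]
    assert r > 0.999
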