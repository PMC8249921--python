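"""Morlet CWT, smoothing, wavelet coherence and phase statistics."""

import numpy as np
import pytest

from cmcsim.coherence import (WaveletParams, cross_wavelet, cwt,
                              peak_coherence_frequency, phase_lead,
                              smooth_spectrum, wavelet_coherence)
from cmcsim.coherence import _morlet_kernel


def _noise(n, seed, fs=None):
    return np.random.default_rng(seed).standard_normal(n)


class TestGrid:
    def test_frequency_grid_contains_one_hertz_and_covers_band(self):
        p = WaveletParams()
        f = p.frequencies()
        assert np.any(np.isclose(f, 1.0))
        assert f[0] == pytest.approx(0.5)
        assert f[-1] <= 45.0
        assert np.all(np.diff(f) > 0)

    def test_scale_frequency_mapping_round_trips(self):
        p = WaveletParams()
        np.testing.assert_allclose(p.fourier_factor / p.scales(),
                                   p.frequencies())


class TestCWT:
    def test_zero_signal_gives_zero_coefficients(self):
        res = cwt(np.zeros(4000), WaveletParams(fmin=2.0), fs=1000.0)
        assert np.all(res.coeffs == 0)

    def test_linearity(self):
        p = WaveletParams(fmin=2.0)
        x, y = _noise(4000, 1), _noise(4000, 2)
        wxy = cwt(x + y, p, fs=1000.0).coeffs
        wx = cwt(x, p, fs=1000.0).coeffs
        wy = cwt(y, p, fs=1000.0).coeffs
        assert np.max(np.abs(wxy - wx - wy)) < 1e-10 * np.max(np.abs(wxy))

    def test_sinusoid_energy_peaks_at_matching_scale(self):
        p = WaveletParams(fmin=2.0, fmax=40.0)
        fs = 500.0
        t = np.arange(int(6 * fs)) / fs
        res = cwt(np.sin(2 * np.pi * 8.0 * t), p, fs=fs)
        power = np.abs(res.coeffs[:, 1000:2000]).mean(axis=1)
        f_peak = res.frequencies[np.argmax(power)]
        nearest = res.frequencies[np.argmin(np.abs(res.frequencies - 8.0))]
        assert f_peak == pytest.approx(nearest)

    def test_matches_direct_time_domain_convolution(self):
        """FFT path vs a literal O(N^2) sum over samples."""
        p = WaveletParams(fmin=4.0, fmax=20.0)
        fs = 200.0
        x = _noise(200, 3)
        res = cwt(x, p, fs=fs)
        k = np.arange(x.size)
        for j, a in enumerate(res.scales[::7]):
            jj = 7 * j
            kern = _morlet_kernel(a, fs, p)
            half = (kern.size - 1) // 2
            direct = np.zeros(x.size, dtype=complex)
            for b in range(x.size):
                for m in range(max(0, b - half), min(x.size, b + half + 1)):
                    # psi((t_m - t_b)/a)* conjugated via the kernel symmetry
                    direct[b] += x[m] * kern[half + (b - m)]
            rel = np.abs(res.coeffs[jj] - direct).max() / np.abs(direct).max()
            assert rel < 1e-8

    def test_short_signal_error_names_offending_scale(self):
        with pytest.raises(ValueError, match="largest scale"):
            cwt(np.zeros(500), WaveletParams(fmin=0.5), fs=1000.0)


class TestCrossWavelet:
    def test_self_product_has_squared_magnitude_and_zero_phase(self):
        res = cwt(_noise(3000, 4), WaveletParams(fmin=2.0), fs=1000.0)
        wxx = cross_wavelet(res, res)
        np.testing.assert_allclose(wxx, np.abs(res.coeffs) ** 2, atol=1e-12)

    def test_swapping_arguments_conjugates(self):
        p = WaveletParams(fmin=2.0)
        wx = cwt(_noise(3000, 5), p, fs=1000.0)
        wy = cwt(_noise(3000, 6), p, fs=1000.0)
        np.testing.assert_allclose(cross_wavelet(wx, wy),
                                   np.conj(cross_wavelet(wy, wx)), atol=1e-12)

    def test_lagged_sinusoids_show_lag_phase(self):
        p = WaveletParams(fmin=2.0, fmax=20.0)
        fs, f0, lag = 500.0, 5.0, 0.02
        t = np.arange(int(8 * fs)) / fs
        wx = cwt(np.sin(2 * np.pi * f0 * t), p, fs=fs)
        wy = cwt(np.sin(2 * np.pi * f0 * (t - lag)), p, fs=fs)
        j = np.argmin(np.abs(wx.frequencies - f0))
        phase = np.angle(cross_wavelet(wx, wy)[j, 1000:3000]).mean()
        assert phase == pytest.approx(2 * np.pi * f0 * lag, rel=0.05)

    def test_grid_mismatch_rejected(self):
        wx = cwt(_noise(3000, 5), WaveletParams(fmin=2.0), fs=1000.0)
        wy = cwt(_noise(3000, 6), WaveletParams(fmin=4.0), fs=1000.0)
        with pytest.raises(ValueError):
            cross_wavelet(wx, wy)


class TestSmoothing:
    def test_constant_field_unchanged(self):
        p = WaveletParams(fmin=2.0)
        field = np.ones((p.frequencies().size, 2000))
        out = smooth_spectrum(field, p, fs=1000.0)
        np.testing.assert_allclose(out, field, atol=1e-12)

    def test_contracts_noise_variance(self):
        p = WaveletParams(fmin=2.0)
        for seed in range(5):
            field = np.random.default_rng(seed).standard_normal(
                (p.frequencies().size, 2000))
            out = smooth_spectrum(field, p, fs=1000.0)
            assert out.var() < field.var()

    def test_commutes_with_scalar_multiplication(self):
        p = WaveletParams(fmin=2.0)
        field = np.random.default_rng(0).standard_normal(
            (p.frequencies().size, 1000))
        np.testing.assert_allclose(smooth_spectrum(3.7 * field, p, fs=1000.0),
                                   3.7 * smooth_spectrum(field, p, fs=1000.0),
                                   atol=1e-12)


class TestCoherence:
    def test_self_coherence_is_one_everywhere(self):
        x = _noise(6000, 7)
        cm = wavelet_coherence(x, x, WaveletParams(fmin=1.0), fs=1000.0)
        np.testing.assert_allclose(cm.coherence, 1.0, atol=1e-9)

    def test_bounded_in_unit_interval(self):
        for seed in (0, 1):
            cm = wavelet_coherence(_noise(8000, seed), _noise(8000, seed + 50),
                                   fs=1000.0)
            assert cm.coherence.min() >= -1e-9
            assert cm.coherence.max() <= 1.0 + 1e-9

    def test_independent_noise_has_low_mean_coherence(self):
        means = []
        for seed in range(10):
            cm = wavelet_coherence(_noise(10000, seed),
                                   _noise(10000, 100 + seed), fs=1000.0)
            means.append(cm.coherence[~cm.coi_mask].mean())
        assert np.mean(means) < 0.5

    def test_shared_component_raises_coherence_at_its_scale(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        common = np.sin(2 * np.pi * 5.0 * t)
        x = common + _noise(t.size, 8)
        y = common + _noise(t.size, 9)
        cm = wavelet_coherence(x, y, fs=fs)
        j5 = np.argmin(np.abs(cm.frequencies - 5.0))
        j20 = np.argmin(np.abs(cm.frequencies - 20.0))
        sel = ~cm.coi_mask[j5] & ~cm.coi_mask[j20]
        assert cm.coherence[j5, sel].mean() > cm.coherence[j20, sel].mean()

    def test_zero_power_region_flagged_not_nan(self):
        x = _noise(6000, 10)
        y = np.zeros(6000)
        cm = wavelet_coherence(x, y, WaveletParams(fmin=2.0), fs=1000.0)
        assert np.isfinite(cm.coherence).all()
        assert cm.zero_power.any()
        assert np.all(cm.coherence[cm.zero_power] == 0.0)


@pytest.fixture(scope="module")
def coupled_3hz():
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    common = np.sin(2 * np.pi * 3.0 * t)
    rng = np.random.default_rng(11)
    x = common + rng.standard_normal(t.size)
    y = common + rng.standard_normal(t.size)
    return wavelet_coherence(x, y, fs=fs)


class TestSummaries:

    def test_peak_frequency_recovers_shared_tone(self, coupled_3hz):
        f = peak_coherence_frequency(coupled_3hz, (2.0, 8.0))
        assert f == pytest.approx(3.0, rel=0.10)

    def test_window_outside_data_rejected(self, coupled_3hz):
        with pytest.raises(ValueError):
            peak_coherence_frequency(coupled_3hz, (50.0, 60.0))

    def test_identical_signals_have_zero_phase(self):
        x = _noise(6000, 12)
        cm = wavelet_coherence(x, x, WaveletParams(fmin=1.0), fs=1000.0)
        assert phase_lead(cm, 4.0, (2.0, 4.0)) == pytest.approx(0.0, abs=1e-9)

    def test_phase_lead_measures_lag_and_flips_sign(self):
        fs, f0, lag = 500.0, 4.0, 0.03
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = np.sin(2 * np.pi * f0 * (t - lag))
        p = WaveletParams(fmin=1.0, fmax=16.0)
        fwd = phase_lead(wavelet_coherence(x, y, p, fs=fs), f0, (3.0, 7.0))
        rev = phase_lead(wavelet_coherence(y, x, p, fs=fs), f0, (3.0, 7.0))
        assert fwd == pytest.approx(2 * np.pi * f0 * lag, rel=0.05)
        assert rev == pytest.approx(-fwd, rel=1e-6)


class TestDelayRecovery:
    """Phase lead at the coupling scale recovers a planted envelope delay."""

    @staticmethod
    def _pair(delta, seed, fs=250.0, duration=12.0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * fs)) / fs
        drive = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * t)
        x = drive + 0.3 * rng.standard_normal(t.size)
        drive_lagged = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * (t - delta))
        y = np.abs(rng.standard_normal(t.size)) * drive_lagged
        return x, y, fs

    @pytest.mark.parametrize("delta", [0.05, 0.1, 0.2])
    def test_planted_delay_recovered_within_20_percent(self, delta):
        estimates = []
        for seed in range(20):
            x, y, fs = self._pair(delta, seed)
            cm = wavelet_coherence(x, y, WaveletParams(fmax=8.0), fs=fs)
            est = phase_lead(cm, 1.0, (2.0, 10.0)) / (2 * np.pi * 1.0)
            estimates.append(est)
        assert np.median(estimates) == pytest.approx(delta, rel=0.20)
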