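"""Analytic oracles and invariants for the feature primitives."""

import numpy as np
import pytest
from scipy import signal as sg

from eegage import features as F

from conftest import sine

FS = 250.0
ALPHA = F.FEATURE_BANDS[2]
BETA = F.FEATURE_BANDS[3]
DELTA = F.FEATURE_BANDS[0]


class TestBandFilter:
    def test_alpha_sine_through_alpha_preserved(self):
        x = sine(10.0, FS, 20.0)
        y = F.band_filter(x, ALPHA, FS)
        assert np.abs(y[500:-500]).max() == pytest.approx(1.0, rel=0.05)

    def test_alpha_sine_through_beta_rejected(self):
        x = sine(10.0, FS, 20.0)
        y = F.band_filter(x, BETA, FS)
        assert np.abs(y[500:-500]).max() < 0.1

    def test_white_noise_through_delta_is_low_frequency(self, rng):
        x = rng.normal(0, 1, int(60 * FS))
        y = F.band_filter(x, DELTA, FS)
        f, p = sg.welch(y, FS, nperseg=int(8 * FS))
        below = p[f < 5.0].sum()
        assert below / p.sum() >= 0.90

    def test_band_above_nyquist_is_error(self):
        with pytest.raises(ValueError):
            F.band_filter(np.zeros(1000), F.BandDefinition("hf", 100.0, 140.0),
                          FS)


class TestEnvelope:
    def test_unit_sine_envelope_is_one(self):
        e = F.envelope(sine(10.0, FS, 10.0))
        assert np.allclose(e[200:-200], 1.0, atol=0.02)

    def test_scaling_is_squared(self):
        e = F.envelope(3.0 * sine(10.0, FS, 10.0))
        assert np.allclose(e[200:-200], 9.0, rtol=0.02)

    def test_tracks_amplitude_modulation(self):
        t = np.arange(int(20 * FS)) / FS
        carrier = np.sin(2 * np.pi * 20.0 * t)
        mod = 1.0 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
        e = F.envelope(mod * carrier)
        target = mod ** 2
        inner = slice(int(2 * FS), -int(2 * FS))
        rmse = np.sqrt(np.mean((e[inner] - target[inner]) ** 2))
        assert rmse / np.sqrt(np.mean(target[inner] ** 2)) < 0.05


class TestAmplitude:
    def test_gaussian_moments(self, rng):
        x = rng.normal(0, 1, 200_000)
        f = F.amplitude_features(x)
        assert f["total_power"][()] == pytest.approx(1.0, abs=0.02)
        assert f["sd"][()] == pytest.approx(1.0, abs=0.02)
        assert f["skewness"][()] == pytest.approx(0.0, abs=0.05)
        assert f["kurtosis"][()] == pytest.approx(3.0, abs=0.1)

    def test_unit_sine_power_is_half(self):
        f = F.amplitude_features(sine(10.0, FS, 20.0))
        assert f["total_power"][()] == pytest.approx(0.5, rel=1e-3)

    def test_zeros_yield_zeros(self):
        f = F.amplitude_features(np.zeros(1000))
        assert f["total_power"][()] == 0.0
        assert f["sd"][()] == 0.0
        assert f["envelope_mean"][()] == 0.0
        assert f["skewness"][()] == 0.0  # undefined -> 0 by convention


class TestReeg:
    def test_constant_signal_all_zero(self):
        f = F.reeg_features(np.ones(int(10 * FS)), FS)
        assert f["mean"][()] == 0.0 and f["median"][()] == 0.0
        assert f["cv"][()] == 0.0 and f["symmetry"][()] == 0.0

    def test_unit_sine_ranges_are_two(self):
        # peak-to-peak slightly under 2 from finite sampling of the peak
        f = F.reeg_features(sine(10.0, FS, 20.0), FS)
        assert f["mean"][()] == pytest.approx(2.0, rel=0.01)
        assert f["sd"][()] == pytest.approx(0.0, abs=1e-6)
        assert f["cv"][()] == pytest.approx(0.0, abs=1e-6)

    def test_scales_linearly(self, rng):
        x = rng.normal(0, 1, int(20 * FS))
        f1 = F.reeg_features(x, FS)
        f2 = F.reeg_features(4.0 * x, FS)
        for k in ("mean", "median", "p5", "p95", "sd"):
            assert f2[k][()] == pytest.approx(4.0 * f1[k][()], rel=1e-9)
        for k in ("cv", "symmetry"):
            assert f2[k][()] == pytest.approx(f1[k][()], rel=1e-9)


class TestWelch:
    def test_sine_peak_at_its_frequency(self):
        psd = F.welch_psd(sine(10.0, FS, 20.0), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(10.0, abs=0.5)

    def test_parseval_consistency(self, rng):
        x = rng.normal(0, 2.0, int(60 * FS))
        psd = F.welch_psd(x, FS)
        df = psd.freqs[1] - psd.freqs[0]
        assert psd.power.sum() * df == pytest.approx(x.var(), rel=0.1)

    def test_two_tones_two_peaks(self):
        x = sine(6.0, FS, 20.0) + sine(20.0, FS, 20.0)
        psd = F.welch_psd(x, FS)
        order = psd.freqs[np.argsort(psd.power)[::-1][:2]]
        assert sorted(np.round(order, 1).tolist()) == [6.0, 20.0]


class TestSpectral:
    def _psd(self, power):
        freqs = np.fft.rfftfreq(500, 1 / FS)
        return F.PSDEstimate(freqs, power, 2.0, 0.5)

    def test_flat_spectrum_entropies_are_one(self):
        freqs = np.fft.rfftfreq(500, 1 / FS)
        power = np.where(F.band_mask(freqs, ALPHA), 2.0, 0.0)
        f = F.spectral_features(self._psd(power), ALPHA)
        assert f["wiener_entropy"][()] == pytest.approx(1.0)
        assert f["shannon_entropy"][()] == pytest.approx(1.0)

    def test_single_bin_entropies_zero_and_edge_there(self):
        freqs = np.fft.rfftfreq(500, 1 / FS)
        power = np.zeros_like(freqs)
        k = np.where(F.band_mask(freqs, ALPHA))[0][4]
        power[k] = 7.0
        f = F.spectral_features(self._psd(power), ALPHA)
        assert f["wiener_entropy"][()] == pytest.approx(0.0, abs=1e-12)
        assert f["shannon_entropy"][()] == pytest.approx(0.0, abs=1e-12)
        assert f["edge_freq"][()] == freqs[k]

    def test_relative_power_partitions_whole_band(self, rng):
        # band-limit a noise signal to W; the four bands tile W exactly
        x = F.band_filter(rng.normal(0, 1, int(120 * FS)), F.WHOLE_BAND, FS)
        psd = F.welch_psd(x, FS)
        total = sum(
            F.spectral_features(psd, b)["relative_power"][()]
            for b in F.FEATURE_BANDS)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_edge_frequency_within_band(self, rng):
        x = rng.normal(0, 1, int(60 * FS))
        psd = F.welch_psd(x, FS)
        for b in F.FEATURE_BANDS:
            e = F.spectral_features(psd, b)["edge_freq"][()]
            assert b.lo <= e < b.hi


class TestBSI:
    freqs = np.fft.rfftfreq(500, 1 / FS)

    def test_identical_hemispheres_zero(self, rng):
        p = rng.uniform(0.1, 1.0, (3, self.freqs.size))
        assert F.bsi(p, p, self.freqs, ALPHA) == 0.0

    def test_one_sided_is_one(self, rng):
        p = rng.uniform(0.1, 1.0, (3, self.freqs.size))
        assert F.bsi(np.zeros_like(p), p, self.freqs, ALPHA) == pytest.approx(1.0)

    def test_triple_ratio_is_half(self):
        p = np.ones((2, self.freqs.size))
        assert F.bsi(p, 3.0 * p, self.freqs, ALPHA) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        a = rng.uniform(0, 1, (4, self.freqs.size))
        b = rng.uniform(0, 1, (4, self.freqs.size))
        ab = F.bsi(a, b, self.freqs, BETA)
        ba = F.bsi(b, a, self.freqs, BETA)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0


class TestEnvelopeXcorr:
    def test_identical_signals_peak_at_zero_lag(self, rng):
        e = np.abs(rng.normal(0, 1, 5000))
        out = F.envelope_xcorr_features(e, e, FS, max_lag=0.1)
        assert out["env_xcorr_max"] == pytest.approx(1.0)
        assert out["env_xcorr_lag"] == 0.0

    def test_constructed_delay_recovered_with_sign(self, rng):
        # right[t] = left[t + d]: the right side runs ahead (leads) by d
        # samples, so the peak sits at positive lag +d per the convention
        d = 12
        base = np.abs(rng.normal(0, 1, 5000 + d))
        left, right = base[:-d], base[d:]
        out = F.envelope_xcorr_features(left[None], right[None], FS,
                                        max_lag=0.2)
        assert out["env_xcorr_lag"] == pytest.approx(d / FS)
        out2 = F.envelope_xcorr_features(right[None], left[None], FS,
                                         max_lag=0.2)
        assert out2["env_xcorr_lag"] == pytest.approx(-d / FS)

    def test_independent_noise_low_correlation(self, rng):
        a = np.abs(rng.normal(0, 1, 20000))
        b = np.abs(rng.normal(0, 1, 20000))
        out = F.envelope_xcorr_features(a, b, FS, max_lag=0.2)
        assert out["env_xcorr_max"] < 0.3


class TestCoherence:
    def test_identical_signals_full_coherence(self, rng):
        x = rng.normal(0, 1, int(60 * FS))
        out = F.coherence_features(x, x, FS, ALPHA)
        assert out["coherence_mean"] == pytest.approx(1.0)

    def test_independent_noise_low_coherence(self, rng):
        x = rng.normal(0, 1, int(120 * FS))
        y = rng.normal(0, 1, int(120 * FS))
        out = F.coherence_features(x, y, FS, ALPHA)
        assert out["coherence_mean"] < 0.2

    def test_shared_tone_peaks_at_tone_frequency(self, rng):
        tone = sine(10.0, FS, 60.0)
        x = tone + 0.5 * rng.normal(0, 1, tone.size)
        y = tone + 0.5 * rng.normal(0, 1, tone.size)
        out = F.coherence_features(x, y, FS, ALPHA)
        assert out["coherence_max_freq"] == pytest.approx(10.0, abs=0.5)


class TestHiguchi:
    def test_line_has_dimension_one(self):
        fd = F.higuchi_fd(np.linspace(0.0, 1.0, 5000))
        assert fd[0] == pytest.approx(1.0, abs=0.05)

    def test_white_noise_has_dimension_two(self, rng):
        fd = F.higuchi_fd(rng.normal(0, 1, 20000))
        assert fd[0] == pytest.approx(2.0, abs=0.1)

    def test_sine_between_one_and_one_and_a_half(self):
        fd = F.higuchi_fd(sine(10.0, FS, 20.0))
        assert 1.0 < fd[0] < 1.5

    def test_scale_invariant(self, rng):
        x = rng.normal(0, 1, 4000)
        assert F.higuchi_fd(x)[0] == pytest.approx(F.higuchi_fd(5 * x)[0],
                                                   rel=1e-9)
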