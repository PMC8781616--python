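"""Filtering, EMD, Hilbert spectral analysis and centroid extraction.

Oracles: the analytic Butterworth magnitude response (squared for zero-phase
filtering), direct correlation against known signal components, periodogram
peak frequencies, and the known frequency of pure tones.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram
from scipy.stats import pearsonr, spearmanr

import hhtecg as hg
from hhtecg.hht import _is_imf, _local_extrema

from conftest import tone_frame

FS = 360.0


def butterworth_gain(freq_hz: float, cutoff_hz: float = 16.0, order: int = 5) -> float:
    """Analytic |H(f)|^2 of an order-n Butterworth low-pass applied twice
    (forward-backward filtering squares the magnitude response)."""
    return float((1.0 + (freq_hz / cutoff_hz) ** (2 * order)) ** -1.0)


def measured_gain(freq_hz: float) -> float:
    frame = tone_frame(freq_hz, duration_s=10.0)
    out = hg.lowpass_filter(frame).samples
    t = frame.times
    mid = slice(round(3 * FS), round(7 * FS))  # away from filtfilt edges
    c = np.sin(2 * np.pi * freq_hz * t[mid])
    s = np.cos(2 * np.pi * freq_hz * t[mid])
    return float(np.hypot(np.dot(out[mid], c), np.dot(out[mid], s)) * 2 / c.size)


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        frame = hg.Frame(np.full(1080, 1.0), FS)
        out = hg.lowpass_filter(frame)
        np.testing.assert_allclose(out.samples, 1.0, atol=1e-9)

    @pytest.mark.parametrize("freq,band", [(5.0, "pass"), (60.0, "stop")])
    def test_pass_and_stop_band(self, freq, band):
        gain = measured_gain(freq)
        if band == "pass":
            assert gain >= 0.99
        else:
            assert gain <= 0.001
        assert gain == pytest.approx(butterworth_gain(freq), abs=1e-4)

    def test_cutoff_above_nyquist_rejected(self):
        frame = tone_frame(5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            hg.lowpass_filter(frame, hg.FilterSpec(cutoff_hz=200.0))

    def test_idempotent_on_band_limited_signal(self):
        frame = tone_frame(5.0, duration_s=10.0)
        once = hg.lowpass_filter(frame)
        twice = hg.lowpass_filter(once)
        mid = slice(round(3 * FS), round(7 * FS))
        a1 = np.sqrt(np.mean(once.samples[mid] ** 2))
        a2 = np.sqrt(np.mean(twice.samples[mid] ** 2))
        assert abs(a2 - a1) / a1 < 1e-3


class TestSiftOnce:
    def test_symmetric_sine_is_its_own_candidate(self):
        x = tone_frame(5.0).samples
        candidate, mean_env = hg.sift_once(x)
        assert np.max(np.abs(mean_env)) < 0.05
        assert pearsonr(candidate, x)[0] > 0.999

    def test_constant_offset_goes_to_mean_envelope(self):
        x = tone_frame(5.0).samples + 5.0
        _, mean_env = hg.sift_once(x)
        assert np.median(np.abs(mean_env - 5.0)) < 0.05

    def test_too_few_extrema_signals_residue(self):
        with pytest.raises(hg.ResidueReached):
            hg.sift_once(np.array([0.0, 1.0, 0.0]))


class TestEMD:
    def test_monotonic_ramp_yields_no_imfs(self):
        frame = hg.Frame(np.linspace(0, 1, 1080), FS)
        s = hg.emd(frame)
        assert len(s) == 0
        np.testing.assert_array_equal(s.residue, frame.samples)

    def test_sine_plus_ramp_separates_components(self):
        t = np.arange(1080) / FS
        sine, ramp = np.sin(2 * np.pi * 8 * t), 0.3 * t
        s = hg.emd(hg.Frame(sine + ramp, FS))
        assert len(s) >= 1
        assert pearsonr(s.imfs[0], sine)[0] > 0.95
        trend = s.residue + sum(s.imfs[1:], np.zeros_like(ramp))
        assert pearsonr(trend, ramp)[0] > 0.95

    def test_two_tone_dominant_frequencies(self):
        t = np.arange(1080) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 1 * t)
        s = hg.emd(hg.Frame(x, FS))
        assert len(s) >= 2
        freqs = []
        for imf in s.imfs[:2]:
            f, p = periodogram(imf, fs=FS)
            freqs.append(f[np.argmax(p)])
        assert freqs[0] == pytest.approx(10.0, abs=1.0)
        assert freqs[1] == pytest.approx(1.0, abs=0.5)

    def test_nonfinite_input_rejected(self):
        x = np.zeros(1080)
        x[5] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            hg.emd(hg.Frame(x, FS))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_completeness_and_mode_conditions_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(720)
        s = hg.emd(hg.Frame(x, FS, duration_s=2.0))
        assert np.max(np.abs(s.reconstruct() - x)) < 1e-8 * np.max(np.abs(x))
        for imf in s.imfs:
            assert _is_imf(imf)
        maxima, minima = _local_extrema(s.residue)
        assert maxima.size < 2 or minima.size < 2


class TestHilbertAnalysis:
    def test_pure_tone_frequency_and_amplitude(self):
        s = hg.emd(tone_frame(5.0))
        hs = hg.hilbert_analysis(s)
        _, freq, amp = hs.entries[0]
        assert np.median(freq) == pytest.approx(5.0, abs=0.1)
        assert np.median(amp) == pytest.approx(1.0, abs=0.02)

    def test_amplitude_linearity(self):
        s = hg.emd(tone_frame(5.0, amplitude=2.0))
        _, _, amp = hg.hilbert_analysis(s).entries[0]
        assert np.median(amp) == pytest.approx(2.0, abs=0.04)

    def test_chirp_has_monotone_instantaneous_frequency(self):
        t = np.arange(1080) / FS
        phase = 2 * np.pi * (2 * t + (8 - 2) / (2 * 3.0) * t**2)  # 2 -> 8 Hz
        s = hg.IMFSet(imfs=[np.sin(phase)], residue=np.zeros(1080),
                      n_sifts=[0], fs=FS)
        times, freq, _ = hg.hilbert_analysis(s).entries[0]
        rho = spearmanr(times, freq)[0]
        assert rho > 0.9

    def test_empty_imf_list_rejected(self):
        s = hg.IMFSet(imfs=[], residue=np.zeros(100), n_sifts=[], fs=FS)
        with pytest.raises(ValueError, match="empty"):
            hg.hilbert_analysis(s)


class TestMarginalSpectrum:
    def test_tone_mass_concentrates_at_tone_frequency(self):
        hs = hg.hilbert_analysis(hg.emd(tone_frame(5.0)))
        mhs = hg.marginal_spectrum(hs, 0)
        near = (mhs.freq_hz >= 4.8) & (mhs.freq_hz <= 5.2)
        assert mhs.energy[near].sum() / mhs.energy.sum() >= 0.95

    def test_energy_conservation_bin_sum_equals_time_sum(self):
        rng = np.random.default_rng(1)
        frame = hg.Frame(rng.standard_normal(1080), FS)
        hs = hg.hilbert_analysis(hg.emd(frame))
        for j in range(len(hs.entries)):
            mhs = hg.marginal_spectrum(hs, j)
            _, _, amp = hs.entries[j]
            expected = np.sum(amp) / FS
            assert mhs.energy.sum() == pytest.approx(expected, rel=1e-9)

    def test_zero_imf_gives_zero_spectrum(self):
        s = hg.IMFSet(imfs=[np.zeros(1080)], residue=np.zeros(1080),
                      n_sifts=[0], fs=FS)
        mhs = hg.marginal_spectrum(hg.hilbert_analysis(s), 0)
        assert np.all(mhs.energy == 0)

    def test_bad_arguments(self):
        hs = hg.hilbert_analysis(hg.emd(tone_frame(5.0)))
        with pytest.raises(ValueError, match="bin_hz"):
            hg.marginal_spectrum(hs, 0, bin_hz=0.0)
        with pytest.raises(IndexError):
            hg.marginal_spectrum(hs, 99)


class TestCentroid:
    def test_tone_centroid_frequency(self):
        hs = hg.hilbert_analysis(hg.emd(tone_frame(5.0)))
        c = hg.mhs_centroid(hg.marginal_spectrum(hs, 0))
        assert c.freq_hz == pytest.approx(5.0, abs=0.2)

    def test_degenerate_zero_spectrum(self):
        mhs = hg.MarginalSpectrum(np.arange(10) * 0.05, np.zeros(10), 3.0)
        c = hg.mhs_centroid(mhs)
        assert (c.freq_hz, c.power) == (0.0, 0.0)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        hs = hg.hilbert_analysis(hg.emd(tone_frame(5.0)))
        mhs = hg.marginal_spectrum(hs, 0)
        base = hg.mhs_centroid(mhs)
        scaled = hg.mhs_centroid(
            hg.MarginalSpectrum(mhs.freq_hz, mhs.energy * scale, mhs.frame_duration_s)
        )
        assert scaled.power == pytest.approx(scale * base.power, rel=1e-9)
        assert scaled.freq_hz == pytest.approx(base.freq_hz, rel=1e-9)

    @pytest.mark.parametrize("f0", [1.0, 3.0, 7.0, 11.0, 14.0])
    def test_tone_recovery_within_five_percent(self, f0):
        hs = hg.hilbert_analysis(hg.emd(tone_frame(f0)))
        c = hg.mhs_centroid(hg.marginal_spectrum(hs, 0))
        assert abs(c.freq_hz - f0) / f0 < 0.05
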