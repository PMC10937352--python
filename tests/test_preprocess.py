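"""Signal-path oracles: filters, Hilbert envelope, running z-score."""

import numpy as np
import pytest
from scipy import signal

from seegspeech.preprocess import (
    BAND_NAMES,
    BAND_ORDER,
    BANDS,
    FEATURE_RATE,
    RAW_RATE,
    RawRecording,
    detrend_and_antialias,
    extract_band,
    extract_high_gamma,
    preprocess_session,
    running_zscore,
)


def tone_recording(freq, amp=1.0, duration=10.0, rate=RAW_RATE, n_channels=1):
    t = np.arange(int(duration * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    return RawRecording(np.tile(x, (n_channels, 1)), rate,
                        [f"ch{i}" for i in range(n_channels)], "s")


def measured_gain(out, amp):
    """Amplitude gain from the RMS of the central portion of a sinusoid."""
    core = out[..., out.shape[-1] // 4: -out.shape[-1] // 4]
    return np.sqrt(2) * core.std() / amp


class TestDetrendAntialias:
    def test_linear_ramp_annihilated(self):
        t = np.arange(20000) / RAW_RATE
        rec = RawRecording((3.0 + 5.0 * t)[None, :], RAW_RATE, ["c"], "s")
        out = detrend_and_antialias(rec)
        assert np.abs(out.samples).max() < 1e-6

    def test_passband_tone_preserved(self):
        out = detrend_and_antialias(tone_recording(100.0))
        assert measured_gain(out.samples, 1.0) == pytest.approx(1.0, abs=0.02)

    def test_stopband_tone_attenuated(self):
        out = detrend_and_antialias(tone_recording(600.0))
        # 600 Hz is in the stopband of the 500 Hz zero-phase low-pass
        assert measured_gain(out.samples, 1.0) < 0.05

    def test_low_rate_rejected(self):
        rec = tone_recording(10.0, rate=1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            detrend_and_antialias(rec)


class TestHighGamma:
    def test_pure_tone_envelope_is_amplitude(self):
        env = extract_high_gamma(tone_recording(100.0, amp=2.5))
        core = env[:, 200:-200]
        assert np.allclose(core, 2.5, rtol=0.05)

    def test_am_tone_recovers_modulation(self):
        # envelope of A*sin(2*pi*100 t)*(1 + 0.5 sin(2*pi*2 t)) is the modulator
        rate, dur, A = RAW_RATE, 10.0, 1.5
        t = np.arange(int(dur * rate)) / rate
        x = A * np.sin(2 * np.pi * 100 * t) * (1 + 0.5 * np.sin(2 * np.pi * 2 * t))
        env = extract_high_gamma(RawRecording(x[None, :], rate, ["c"], "s"))
        t200 = np.arange(env.shape[-1]) / FEATURE_RATE
        expected = A * (1 + 0.5 * np.sin(2 * np.pi * 2 * t200))
        sl = slice(100, -100)  # trim filter edges
        rms_err = np.sqrt(np.mean((env[0, sl] - expected[sl]) ** 2))
        assert rms_err / expected[sl].mean() < 0.05

    def test_zero_in_zero_out(self):
        rec = RawRecording(np.zeros((2, 8000)), RAW_RATE, ["a", "b"], "s")
        assert np.allclose(extract_high_gamma(rec), 0.0)


class TestBandpass:
    def test_passband_gains(self):
        assert measured_gain(extract_band(tone_recording(10.0), "1-30 Hz"), 1.0) \
            == pytest.approx(1.0, abs=0.02)
        assert measured_gain(extract_band(tone_recording(50.0), "30-70 Hz"), 1.0) \
            == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("freq, band", [(50.0, "1-30 Hz"), (20.0, "30-70 Hz")])
    def test_stopband_matches_analytic_butterworth(self, freq, band):
        """Measured attenuation equals the designed filter's |H(f)|^2 (zero-phase).

        Probe tones sit well below the 100 Hz output Nyquist so the polyphase
        decimator's own roll-off does not enter the measurement.
        """
        out = extract_band(tone_recording(freq, duration=30.0), band)
        sos = signal.butter(BAND_ORDER, BANDS[band], btype="bandpass",
                            fs=RAW_RATE, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=RAW_RATE)
        expected = np.abs(h[0]) ** 2  # forward-backward application squares |H|
        got = measured_gain(out, 1.0)
        assert got == pytest.approx(expected, rel=0.01)

    def test_unsupported_band_rejected(self):
        with pytest.raises(ValueError):
            extract_band(tone_recording(10.0), "70-150 Hz")
        with pytest.raises(ValueError):
            extract_band(tone_recording(10.0), "8-12 Hz")

    def test_band_paths_share_time_axis(self):
        rec = tone_recording(20.0, duration=5.0)
        low = extract_band(rec, "1-30 Hz")
        mid = extract_band(rec, "30-70 Hz")
        hg = extract_high_gamma(rec)
        assert low.shape == mid.shape == hg.shape

    def test_zero_phase_alignment_impulse(self):
        """An impulse peaks at the same output index through all three paths."""
        x = np.zeros((1, 40000))
        x[0, 20000] = 1.0
        rec = RawRecording(x, RAW_RATE, ["c"], "s")
        peaks = [
            int(np.argmax(np.abs(extract_band(rec, "1-30 Hz")))),
            int(np.argmax(np.abs(extract_band(rec, "30-70 Hz")))),
            int(np.argmax(extract_high_gamma(rec))),
        ]
        assert max(peaks) - min(peaks) <= 1

    def test_stopband_leakage_below_one_percent(self, rng):
        """Broadband noise: out-of-band power in each band output is < 1%."""
        x = rng.standard_normal((1, int(60 * RAW_RATE)))
        rec = RawRecording(x, RAW_RATE, ["c"], "s")
        for band in ("1-30 Hz", "30-70 Hz"):
            out = extract_band(rec, band)[0]
            freqs, psd = signal.welch(out, fs=FEATURE_RATE, nperseg=2048)
            lo, hi = BANDS[band]
            inband = (freqs >= lo) & (freqs <= hi)
            margin = (freqs < lo * 0.5) | (freqs > min(hi * 1.5, 99))
            assert psd[margin].sum() / psd[inband].sum() < 0.01


class TestRunningZscore:
    def test_white_noise_normalized(self, rng):
        x = 3.0 + 2.0 * rng.standard_normal((1, 1, 12000))
        z = running_zscore(x, FEATURE_RATE, 30.0)
        assert abs(z.mean()) < 0.05
        assert abs(z.var() - 1.0) < 0.1

    def test_constant_channel_is_all_zeros(self):
        z = running_zscore(np.full((1, 1, 8000), 7.5), FEATURE_RATE, 30.0)
        assert np.all(z == 0.0)
        assert np.all(np.isfinite(z))

    def test_gain_step_invariance(self, rng):
        """Variance is restored to ~1 in both halves after a mid-session gain step."""
        n = 24000  # 120 s
        x = rng.standard_normal(n)
        x[n // 2:] *= 2.0
        z = running_zscore(x[None, None, :], FEATURE_RATE, 30.0)[0, 0]
        margin = 4000  # keep clear of the step and session edges
        v1 = z[margin:n // 2 - margin].var()
        v2 = z[n // 2 + margin:-margin].var()
        assert v1 == pytest.approx(1.0, abs=0.1)
        assert v2 == pytest.approx(1.0, abs=0.1)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="window"):
            running_zscore(np.zeros((1, 1, 100)), FEATURE_RATE, 30.0)


class TestPreprocessSession:
    def test_output_shape_and_determinism(self, rng):
        x = rng.standard_normal((2, int(60 * RAW_RATE)))
        rec = RawRecording(x, RAW_RATE, ["a", "b"], "s1")
        ft1 = preprocess_session(rec)
        ft2 = preprocess_session(rec)
        assert ft1.values.shape == (2, 3, 12000)
        assert ft1.band_names == BAND_NAMES
        assert ft1.rate == FEATURE_RATE
        assert np.array_equal(ft1.values, ft2.values)  # bit-identical

    def test_zero_input_gives_zero_features(self):
        rec = RawRecording(np.zeros((1, int(60 * RAW_RATE))), RAW_RATE, ["a"], "s")
        ft = preprocess_session(rec)
        assert ft.values.shape == (1, 3, 12000)
        assert np.allclose(ft.values, 0.0)
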