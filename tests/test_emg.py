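"""EMG conditioning: zero-lag filtering, rectification, envelope, MVC scaling."""

import numpy as np
import pytest
from scipy import signal as sps

from emgforce import EnvelopeConfig, UniformSeries, envelope, normalize_mvc, rectify, zero_lag_butterworth
from emgforce.emg import butter_coefficients, moving_average


FS = 2048.0


def sine(freq, duration=4.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return UniformSeries(dt=1 / fs, values=amp * np.sin(2 * np.pi * freq * t))


class TestZeroLagButterworth:
    def test_lowpass_passes_dc(self):
        x = UniformSeries(dt=1 / FS, values=np.full(4096, 3.7))
        y = zero_lag_butterworth(x, 2.0, 2, "low")
        assert np.allclose(y.values, 3.7, atol=1e-9)

    def test_highpass_kills_dc(self):
        x = UniformSeries(dt=1 / FS, values=np.full(4096, 3.7))
        y = zero_lag_butterworth(x, 30.0, 4, "high")
        assert np.max(np.abs(y.values)) < 1e-6

    @pytest.mark.parametrize("cutoff,order,kind", [(30.0, 4, "low"), (100.0, 2, "low")])
    def test_attenuation_matches_frequency_response_oracle(self, cutoff, order, kind):
        """Forward-backward filtering squares the single-pass magnitude:
        at the cutoff a unit sinusoid comes out at |H(fc)|^2 ~ 0.5."""
        x = sine(cutoff, duration=8.0)
        y = zero_lag_butterworth(x, cutoff, order, kind)
        # oracle: squared magnitude of the half-order design at the cutoff
        b, a = butter_coefficients(cutoff, order // 2, kind, FS)
        _, h = sps.freqz(b, a, worN=[cutoff], fs=FS)
        expected = np.abs(h[0]) ** 2
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        measured = np.max(np.abs(y.values[mid]))
        assert expected == pytest.approx(0.5, abs=0.02)
        assert measured == pytest.approx(expected, rel=0.02)

    def test_zero_phase_keeps_symmetric_peak_index(self):
        t = np.arange(4096) / FS
        x = UniformSeries(dt=1 / FS, values=np.exp(-((t - 1.0) ** 2) / (2 * 0.05**2)))
        y = zero_lag_butterworth(x, 10.0, 4, "low")
        assert int(np.argmax(y.values)) == int(np.argmax(x.values))

    def test_single_direction_variant_lags(self):
        t = np.arange(4096) / FS
        x = UniformSeries(dt=1 / FS, values=np.exp(-((t - 1.0) ** 2) / (2 * 0.05**2)))
        y = zero_lag_butterworth(x, 10.0, 4, "low", zero_phase=False)
        assert int(np.argmax(y.values)) > int(np.argmax(x.values))

    def test_cutoff_above_nyquist_rejected(self):
        x = sine(5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            zero_lag_butterworth(x, FS, 4, "low")

    def test_too_short_series_rejected(self):
        x = UniformSeries(dt=1 / FS, values=np.zeros(5))
        with pytest.raises(ValueError, match="short"):
            zero_lag_butterworth(x, 30.0, 4, "high")


class TestRectifyAndNormalize:
    def test_rectify_is_absolute_value_and_idempotent(self, make_series):
        x = make_series([-1.0, 2.0, -3.0])
        y = rectify(x)
        assert np.array_equal(y.values, [1.0, 2.0, 3.0])
        assert np.array_equal(rectify(y).values, y.values)

    def test_normalize_divides_and_composes(self, make_series):
        x = make_series([0.0, 2.0, 4.0])
        assert np.allclose(normalize_mvc(x, 4.0).values, [0.0, 0.5, 1.0])
        twice = normalize_mvc(normalize_mvc(x, 2.0), 3.0)
        once = normalize_mvc(x, 6.0)
        assert np.allclose(twice.values, once.values)

    def test_normalize_rejects_nonpositive_peak(self, make_series):
        with pytest.raises(ValueError):
            normalize_mvc(make_series([1.0]), 0.0)


class TestEnvelope:
    def test_constant_preserved_by_both_methods(self):
        x = UniformSeries(dt=1 / FS, values=np.full(4096, 0.8))
        lp = envelope(x, EnvelopeConfig())
        mav = envelope(x, EnvelopeConfig(mav_window=0.25))
        assert np.allclose(lp.values, 0.8, atol=1e-9)
        assert np.allclose(mav.values, 0.8, atol=1e-12)

    def test_mav_impulse_gives_window_plateau(self):
        x = UniformSeries(dt=1.0, values=np.r_[np.zeros(10), 1.0, np.zeros(10)])
        y = moving_average(x, 5.0)
        assert y.values.max() == pytest.approx(0.2)
        assert np.sum(np.isclose(y.values, 0.2)) == 5

    def test_mav_window_below_one_sample_rejected(self):
        x = UniformSeries(dt=1.0, values=np.zeros(10))
        with pytest.raises(ValueError, match="sample"):
            moving_average(x, 0.2)

    def test_rectified_sine_lowpasses_to_mean_two_over_pi(self):
        """The 2 Hz envelope of a rectified 50 Hz sinusoid is its mean, 2/pi."""
        x = rectify(sine(50.0, duration=6.0))
        y = envelope(x, EnvelopeConfig())
        mid = slice(len(x) // 3, 2 * len(x) // 3)
        assert np.mean(y.values[mid]) == pytest.approx(2 / np.pi, rel=0.02)

    def test_envelope_nonnegative_for_nonnegative_input(self, rng):
        x = rectify(UniformSeries(dt=1 / FS, values=rng.normal(size=8192)))
        y = envelope(x, EnvelopeConfig(mav_window=0.3))
        assert y.values.min() >= 0.0

    def test_processing_scales_linearly_with_amplitude(self, rng):
        from emgforce import process_emg

        raw = UniformSeries(dt=1 / FS, values=rng.normal(size=8192))
        one = process_emg(raw, EnvelopeConfig())
        three = process_emg(raw.with_values(3.0 * raw.values), EnvelopeConfig())
        assert np.allclose(three.values, 3.0 * one.values, rtol=1e-9, atol=1e-12)


def test_envelope_config_rejects_inverted_cutoffs():
    with pytest.raises(ValueError):
        EnvelopeConfig(hp_cutoff=1.0, lp_cutoff=2.0)
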