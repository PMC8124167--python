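"""Unit and property tests for the validation metrology chain."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit.exceptions import (
    InsufficientDataError,
    NoOscillationError,
    ValidationError,
)
from tremorkit.metrology import (
    actual_sample_rate,
    compare_measurement,
    dominant_frequency,
    noise_statistics,
    oscillation_amplitude,
    reference_to_acceleration,
)
from tremorkit.recordings import STANDARD_GRAVITY, ReferenceRecording
from tremorkit.simulate import IDEAL_WATCH, generate_shaker_campaign

RATE = 100.0


def _reference(velocity_mm_s, rate=RATE, gain=1.0):
    t = np.arange(len(velocity_mm_s)) / rate
    return ReferenceRecording(
        timestamps=t, velocity=np.asarray(velocity_mm_s) * gain, gain=gain, rate=rate
    )


# --------------------------------------------------------------------------
# reference conversion
# --------------------------------------------------------------------------

class TestReferenceToAcceleration:
    def test_constant_velocity_gives_zero_acceleration(self):
        acc = reference_to_acceleration(_reference(np.full(500, 7.3)))
        assert acc.shape == (500,)
        assert np.allclose(acc, 0.0, atol=1e-10)

    def test_sinusoid_closed_form_amplitude(self):
        # velocity A sin(2 pi f t) mm/s -> acceleration amplitude
        # 2 pi f A / (1000 * 9.81) g
        f, amp = 5.0, 31.24
        t = np.arange(0, 20, 1 / RATE)
        ref = _reference(amp * np.sin(2 * np.pi * f * t))
        acc = reference_to_acceleration(ref)
        expected_amp = 2 * np.pi * f * amp / (1000 * STANDARD_GRAVITY)
        assert expected_amp == pytest.approx(0.1001, abs=2e-4)
        expected = expected_amp * np.cos(2 * np.pi * f * t)
        sl = slice(50, -50)
        assert np.allclose(acc[sl], expected[sl], atol=0.01 * expected_amp)

    def test_gain_cancellation(self):
        t = np.arange(0, 10, 1 / RATE)
        v = 5.0 * np.sin(2 * np.pi * 4.0 * t)
        one = reference_to_acceleration(_reference(v, gain=1.0))
        two = reference_to_acceleration(_reference(v, gain=2.0))
        assert np.allclose(one, two)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            reference_to_acceleration(_reference([1.0, 2.0]))

    def test_nonuniform_timestamps_raise(self):
        ref = _reference(np.sin(np.arange(100)))
        ref.timestamps = ref.timestamps.copy()
        ref.timestamps[50] += 0.005  # half the sampling interval
        with pytest.raises(ValidationError):
            reference_to_acceleration(ref)

    @pytest.mark.parametrize("freq", [3.0, 7.0, 11.0, 15.0])
    def test_round_trip_recovers_amplitude_within_1pct(self, freq):
        # acceleration amplitude in g -> analytic velocity -> back
        amp_g = 0.05
        t = np.arange(0, 20, 1 / RATE)
        omega = 2 * np.pi * freq
        v_mm_s = -(amp_g * STANDARD_GRAVITY / omega) * np.cos(omega * t) * 1000
        acc = reference_to_acceleration(_reference(v_mm_s))
        est, _ = oscillation_amplitude(acc, RATE)
        assert est == pytest.approx(amp_g, rel=0.01)


# --------------------------------------------------------------------------
# sample rate
# --------------------------------------------------------------------------

class TestActualSampleRate:
    def test_uniform_100hz(self):
        assert actual_sample_rate(np.arange(2001) * 0.01) == pytest.approx(100.0)

    def test_deficit_rate(self):
        assert actual_sample_rate(np.arange(1988) / 99.4) == pytest.approx(99.4)

    def test_non_increasing_raises(self):
        with pytest.raises(ValidationError):
            actual_sample_rate([0.0, 0.01, 0.01, 0.03])

    def test_single_timestamp_raises(self):
        with pytest.raises(InsufficientDataError):
            actual_sample_rate([0.0])


# --------------------------------------------------------------------------
# dominant frequency
# --------------------------------------------------------------------------

def _sinusoid(freq, rate=RATE, duration=20.0, phase=0.0, amp=1.0):
    t = np.arange(0, duration, 1 / rate)
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestDominantFrequency:
    def test_on_bin_sinusoid(self):
        assert dominant_frequency(_sinusoid(5.0), RATE) == pytest.approx(5.00)

    def test_constant_signal_raises(self):
        with pytest.raises(NoOscillationError):
            dominant_frequency(np.full(100, 2.5), RATE)

    def test_coarse_bin_spacing_warns_and_pads_to_signal_length(self):
        x = _sinusoid(5.0, duration=200.0)  # 20000 samples > 100/0.01
        with pytest.warns(UserWarning):
            f = dominant_frequency(x, RATE, bin_spacing=0.01)
        assert f == pytest.approx(5.0, abs=0.01)

    def test_rate_mismatch_scales_frequency(self):
        # 15 Hz motion sampled at 99.4 Hz but analyzed assuming 100 Hz
        # appears at 15 * 100 / 99.4 = 15.0905, snapped to the 0.01 grid.
        t = np.arange(int(20 * 99.4)) / 99.4
        x = np.sin(2 * np.pi * 15.0 * t)
        assert dominant_frequency(x, 100.0) == pytest.approx(15.09, abs=1e-9)

    @pytest.mark.parametrize(
        "freq,actual,analyzed",
        [(5.0, 99.6, 100.0), (10.0, 99.4, 100.0), (15.0, 99.6, 99.6), (8.0, 100.0, 99.4)],
    )
    def test_frequency_scaling_law(self, freq, actual, analyzed):
        t = np.arange(int(20 * actual)) / actual
        x = np.sin(2 * np.pi * freq * t + 0.3)
        got = dominant_frequency(x, analyzed)
        assert abs(got - freq * analyzed / actual) <= 0.01 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        freq=st.floats(3.0, 15.0),
        phase=st.floats(0.0, 6.28),
    )
    def test_output_lies_on_bin_grid(self, freq, phase):
        f = dominant_frequency(_sinusoid(freq, phase=phase), RATE)
        assert round(f * 100) == pytest.approx(f * 100, abs=1e-9)

    def test_dense_dft_oracle_agreement(self):
        # padded-FFT argmax must track the dense-DFT argmax to half a bin;
        # the discrete oracle adds up to half its own grid step
        rng = np.random.default_rng(11)
        t = np.arange(0, 20, 1 / RATE)
        step = 1e-4
        for _ in range(30):
            freq = rng.uniform(3, 15)
            x = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            got = dominant_frequency(x, RATE)
            grid = np.arange(freq - 0.1, freq + 0.1, step)
            mags = np.abs(np.exp(-2j * np.pi * grid[:, None] * t) @ (x - x.mean()))
            dense = grid[np.argmax(mags)]
            assert abs(got - dense) <= 0.005 + step / 2


# --------------------------------------------------------------------------
# oscillation amplitude
# --------------------------------------------------------------------------

class TestOscillationAmplitude:
    def test_clean_sinusoid(self):
        mean, sd = oscillation_amplitude(_sinusoid(5.0, amp=0.01), RATE)
        assert mean == pytest.approx(0.01, rel=5e-3)
        assert sd < 1e-4

    def test_flat_signal_raises(self):
        with pytest.raises(NoOscillationError):
            oscillation_amplitude(np.zeros(2000), RATE)

    def test_insufficient_periods_raises(self):
        # 2 s at 3 Hz holds only ~6 periods
        with pytest.raises(InsufficientDataError):
            oscillation_amplitude(_sinusoid(3.0, duration=2.0), RATE)

    @pytest.mark.parametrize("freq", [3.0, 6.0, 9.0, 12.0, 15.0])
    @pytest.mark.parametrize("amp", [0.002, 0.01, 0.1])
    def test_unbiased_on_noiseless_sinusoids(self, freq, amp):
        x = _sinusoid(freq, amp=amp, phase=1.1)
        mean, _ = oscillation_amplitude(x, RATE)
        assert mean == pytest.approx(amp, rel=0.01)

    def test_noise_robustness_monte_carlo(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = _sinusoid(5.0, amp=0.01) + rng.normal(0, 5e-4, 2000)
            mean, _ = oscillation_amplitude(x, RATE)
            assert abs(mean - 0.01) < 0.002


# --------------------------------------------------------------------------
# noise statistics
# --------------------------------------------------------------------------

class TestNoiseStatistics:
    def test_pure_dc(self):
        stats = noise_statistics(np.full(2000, 1.5e-4), RATE)
        assert stats.zero_g_offset == pytest.approx(1.5e-4)
        assert stats.rms == pytest.approx(0.0, abs=1e-12)
        assert stats.psd_integral == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(8)
        sigma = 5e-4
        x = rng.normal(2e-4, sigma, 4000)
        stats = noise_statistics(x, RATE)
        assert stats.rms == pytest.approx(sigma, rel=0.10)
        assert stats.psd_integral == pytest.approx(x.var(), rel=0.15)

    def test_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            noise_statistics(np.ones(10), RATE)


# --------------------------------------------------------------------------
# measurement comparison
# --------------------------------------------------------------------------

class TestCompareMeasurement:
    def test_ideal_sensor_has_no_deviation(self):
        (m,) = generate_shaker_campaign(
            protocol=[(5.0, 0.01)], sensor_models=[IDEAL_WATCH], seed=0
        )
        (rec,) = compare_measurement(m)
        assert rec.freq_deviation_nominal == 0.0
        # the timestamp-derived rate carries 1 ulp of float residue
        assert abs(rec.freq_deviation_corrected) < 1e-9
        # both amplitude estimates are numerically exact to well under the
        # 1% unbiasedness budget, so their difference stays below 2% of A
        assert abs(rec.amp_deviation) < 2e-4
        assert rec.freq_ref == pytest.approx(5.0)
        assert rec.amp_ref == pytest.approx(0.01, rel=0.01)

    def test_zero_vibration_is_rejected(self):
        (m,) = generate_shaker_campaign(
            protocol=[(0.0, 0.0)], sensor_models=[IDEAL_WATCH], seed=0
        )
        with pytest.raises(ValidationError):
            compare_measurement(m)

    def test_campaign_corrected_frequency_bound(self, campaign_deviations):
        devs = [abs(r.freq_deviation_corrected) for r in campaign_deviations]
        assert max(devs) <= 0.01 + 1e-9
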