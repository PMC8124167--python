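"""Tests of the engineered feature extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tremorkit.exceptions import InsufficientDataError
from tremorkit.features import (
    PERCENTILES,
    acceleration_sd,
    amplitude_percentiles,
    build_feature_table,
    euclidean_norm,
    feature_schema,
    fft_poly_features,
    side_dominance,
    symptom_count,
)
from tremorkit.recordings import TimestampedRecording
from tremorkit.simulate import EXAM_STEPS, WRISTS, ExamRecordingSet


def _recording(values: np.ndarray, rate: float = 100.0) -> TimestampedRecording:
    values = np.atleast_2d(values)
    return TimestampedRecording(
        timestamps=np.arange(values.shape[0]) / rate,
        acceleration=values,
        nominal_rate=rate,
    )


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

class TestEuclideanNorm:
    def test_3_4_5(self):
        assert euclidean_norm(np.array([[3.0, 4.0, 0.0]]))[0] == pytest.approx(5.0)

    def test_zero(self):
        assert np.all(euclidean_norm(np.zeros((10, 3))) == 0.0)

    def test_single_axis_absolute_value(self):
        acc = np.zeros((50, 3))
        acc[:, 1] = np.sin(np.arange(50))
        assert np.allclose(euclidean_norm(acc), np.abs(acc[:, 1]))


class TestAmplitudePercentiles:
    def test_constant_series(self):
        assert np.allclose(amplitude_percentiles(np.full(20, 3.3)), 3.3)

    def test_uniform_grid(self):
        assert np.allclose(
            amplitude_percentiles(np.arange(101.0)), np.arange(30.0, 75.0, 5.0)
        )

    def test_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            amplitude_percentiles(np.arange(5.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        x=hnp.arrays(
            float, st.integers(9, 60),
            elements=st.floats(-1e3, 1e3, allow_nan=False),
        )
    )
    def test_output_sorted_length_nine(self, x):
        p = amplitude_percentiles(x)
        assert p.shape == (9,)
        assert np.all(np.diff(p) >= 0)


class TestSideDominance:
    def test_identical_sides(self):
        x = np.abs(np.sin(np.arange(100)))
        assert side_dominance(x, x) == pytest.approx(1.0)

    def test_double_left(self):
        x = np.abs(np.sin(np.arange(100))) + 0.1
        assert side_dominance(2 * x, x) == pytest.approx(2.0)

    def test_swap_gives_reciprocal(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200) + 0.1, rng.random(200) + 0.1
        assert side_dominance(a, b) == pytest.approx(1.0 / side_dominance(b, a))

    def test_degenerate_denominator_floored(self):
        with pytest.warns(UserWarning):
            ratio = side_dominance(np.ones(10), np.zeros(10))
        assert np.isfinite(ratio) and ratio > 0


class TestAccelerationSd:
    def test_constant(self):
        assert acceleration_sd(np.full(10, 2.0)) == 0.0

    def test_two_values_closed_form(self):
        a, b = 0.3, 1.1
        assert acceleration_sd(np.array([a, b])) == pytest.approx(abs(a - b) / np.sqrt(2))

    def test_white_noise_recovers_sigma(self):
        x = np.random.default_rng(4).normal(0, 0.02, 2000)
        assert acceleration_sd(x) == pytest.approx(0.02, rel=0.10)

    def test_single_value_raises(self):
        with pytest.raises(InsufficientDataError):
            acceleration_sd(np.array([1.0]))


class TestFftPolyFeatures:
    def test_white_noise_flat_spectrum_small_coefficients(self):
        rng = np.random.default_rng(6)
        acc = np.zeros((2000, 3))
        acc[:, 0] = 5.0 + rng.normal(0, 1e-3, 2000)  # DC keeps the norm linear
        coeffs = fft_poly_features(_recording(acc))
        assert coeffs.shape == (3,)
        # unit-max-normalized flat spectrum: the fitted trend is tiny
        assert abs(coeffs[0]) < 0.05
        assert abs(coeffs[1]) < 0.01
        assert abs(coeffs[2]) < 0.001

    def test_exact_cubic_spectrum_recovered(self):
        # synthesize a series whose amplitude spectrum IS a known cubic over
        # the fit band, then check the coefficients are recovered exactly
        n, rate = 2000, 100.0
        freqs = np.fft.rfftfreq(n, 1 / rate)
        # strictly positive over the band (spectral magnitudes cannot be
        # negative): min over [0.5, 20] Hz is ~6.2 at 20 Hz
        cubic = 5.0 + 0.3 * freqs - 0.02 * freqs**2 + 0.0004 * freqs**3
        band = (freqs >= 0.5) & (freqs <= 20.0)
        mag = np.zeros_like(freqs)
        mag[band] = cubic[band]
        rng = np.random.default_rng(1)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, freqs.size))
        series = np.fft.irfft(mag * phases, n)
        acc = np.zeros((n, 3))
        acc[:, 0] = 50.0 + series  # large DC so the norm equals DC + series
        got = fft_poly_features(_recording(acc))
        scale = cubic[band].max()
        expected = np.array([0.3, -0.02, 0.0004]) / scale
        assert np.allclose(got, expected, rtol=1e-4, atol=1e-7)

    def test_independent_least_squares_oracle(self):
        rng = np.random.default_rng(9)
        acc = rng.normal(0, 0.01, (1500, 3)) + np.array([0.0, 0.0, 1.0])
        rec = _recording(acc)
        got = fft_poly_features(rec)
        # oracle: rebuild the normalized spectrum and solve the normal
        # equations directly
        norm = euclidean_norm(rec)
        x = norm - norm.mean()
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, 1 / 100.0)
        mask = (freqs >= 0.5) & (freqs <= 20.0)
        V = np.vander(freqs[mask], 4, increasing=True)
        coef, *_ = np.linalg.lstsq(V, spec[mask] / spec[mask].max(), rcond=None)
        assert np.allclose(got, coef[1:], rtol=1e-6, atol=1e-12)

    def test_per_axis_shape(self, small_cohort):
        rec = small_cohort[0].recordings[("1a", "left")]
        assert fft_poly_features(rec, per_axis=True).shape == (3, 3)


class TestSymptomCount:
    @pytest.mark.parametrize(
        "answers,expected",
        [([False] * 30, 0), ([True] * 5 + [False] * 25, 5), ([True] * 30, 30)],
    )
    def test_counts(self, answers, expected):
        assert symptom_count(answers) == expected

    def test_missing_treated_as_no_with_warning(self):
        answers = [True, None, float("nan")] + [False] * 27
        with pytest.warns(UserWarning):
            assert symptom_count(answers) == 1


# --------------------------------------------------------------------------
# feature table
# --------------------------------------------------------------------------

class TestBuildFeatureTable:
    def test_schema_size_and_no_missing(self, small_cohort, cohort_features):
        names, groups = feature_schema()
        assert len(names) == 303
        assert set(groups.values()) == {
            "medical_history", "symptoms", "amplitude_distribution",
            "side_dominance", "sd", "fft",
        }
        X, y = build_feature_table(small_cohort)
        assert X.shape == (len(small_cohort), 303)
        assert list(X.columns) == names
        assert not X.isna().any().any()
        Xf, yf = cohort_features
        assert Xf.shape == (450, 303)
        assert not Xf.isna().any().any()

    def test_row_order_follows_cohort_order(self, small_cohort):
        X, y = build_feature_table(small_cohort)
        Xp, yp = build_feature_table(small_cohort[::-1])
        pd.testing.assert_frame_equal(X.iloc[::-1], Xp)
        assert list(y.iloc[::-1]) == list(yp)

    def test_scale_equivariance(self, small_cohort):
        exam = small_cohort[0]
        k = 2.5
        scaled = ExamRecordingSet(
            participant=exam.participant,
            recordings={
                key: TimestampedRecording(
                    timestamps=rec.timestamps,
                    acceleration=rec.acceleration * k,
                    nominal_rate=rec.nominal_rate,
                    step_id=rec.step_id,
                    wrist=rec.wrist,
                )
                for key, rec in exam.recordings.items()
            },
        )
        X1, _ = build_feature_table([exam])
        X2, _ = build_feature_table([scaled])
        _, groups = feature_schema()
        for name in X1.columns:
            g = groups[name]
            if g in ("amplitude_distribution", "sd"):
                assert X2[name].iloc[0] == pytest.approx(k * X1[name].iloc[0], rel=1e-9)
            elif g in ("side_dominance", "fft"):
                assert X2[name].iloc[0] == pytest.approx(X1[name].iloc[0], rel=1e-6)

    def test_wrist_swap_inverts_dominance(self, small_cohort):
        exam = small_cohort[0]
        swapped = ExamRecordingSet(
            participant=exam.participant,
            recordings={
                (step, {"left": "right", "right": "left"}[wrist]): rec
                for (step, wrist), rec in exam.recordings.items()
            },
        )
        X1, y1 = build_feature_table([exam])
        X2, y2 = build_feature_table([swapped])
        assert list(y1) == list(y2)
        for step in EXAM_STEPS:
            assert X2[f"s{step}_dominance"].iloc[0] == pytest.approx(
                1.0 / X1[f"s{step}_dominance"].iloc[0], rel=1e-9
            )
            for w_from, w_to in (("left", "right"), ("right", "left")):
                assert X2[f"s{step}_{w_to}_sd"].iloc[0] == pytest.approx(
                    X1[f"s{step}_{w_from}_sd"].iloc[0]
                )

    def test_missing_recording_imputed_by_cohort_median(self, small_cohort):
        cohort = [
            ExamRecordingSet(
                participant=e.participant,
                recordings=dict(e.recordings),
                require_complete=False,
            )
            for e in small_cohort
        ]
        del cohort[0].recordings[("3", "left")]
        with pytest.warns(UserWarning, match="imputing"):
            X, _ = build_feature_table(cohort)
        assert not X.isna().any().any()
        ref = build_feature_table(list(small_cohort)[1:])[0]
        assert X["s3_left_sd"].iloc[0] == pytest.approx(
            np.median(ref["s3_left_sd"]), rel=1e-9
        )

    def test_cohort_of_one_with_missing_skips_imputation(self, small_cohort):
        lone = ExamRecordingSet(
            participant=small_cohort[0].participant,
            recordings=dict(small_cohort[0].recordings),
            require_complete=False,
        )
        del lone.recordings[("3", "left")]
        with pytest.warns(UserWarning, match="cohort of one"):
            X, _ = build_feature_table([lone])
        assert X["s3_left_sd"].isna().all()
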