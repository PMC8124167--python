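"""Engineered time-series features for disease classification.

For every examination step and wrist the Euclidean norm of the triaxial
acceleration is reduced to:

* nine amplitude-distribution percentiles (30th-70th in 5% steps),
* the sample standard deviation,
* three polynomial coefficients summarising the amplitude spectrum
  (a degree-3 fit over 0.5-20 Hz of the unit-maximum-normalized spectrum of
  the mean-removed norm; the constant term is dropped),

plus one tremor side-dominance ratio per step (90th percentile of the
mean-removed left norm over the right) and six questionnaire features
(age, height, weight, family history, alcohol effect on tremor, and the
number of "yes" answers on the 30-item non-motor-symptom questionnaire).

With the default 11-step protocol this yields
``11 * (2 * 13 + 1) + 6 = 303`` named features per participant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ValidationError
from .metrology import actual_sample_rate
from .recordings import TimestampedRecording
from .simulate import EXAM_STEPS, WRISTS, ExamRecordingSet

__all__ = [
    "FEATURE_GROUPS",
    "PERCENTILES",
    "acceleration_sd",
    "amplitude_percentiles",
    "build_feature_table",
    "euclidean_norm",
    "feature_schema",
    "fft_poly_features",
    "side_dominance",
    "symptom_count",
]

PERCENTILES = tuple(range(30, 75, 5))  # 30..70 in 5% steps

FEATURE_GROUPS = (
    "medical_history",
    "symptoms",
    "amplitude_distribution",
    "side_dominance",
    "sd",
    "fft",
)

#: Frequency band (Hz) over which the spectrum polynomial is fitted;
#: covers the clinically documented tremor range with margin, excluding DC.
FFT_FIT_BAND = (0.5, 20.0)

_DOMINANCE_FLOOR = 1e-6  # g, guards against a degenerate denominator


def euclidean_norm(rec: TimestampedRecording | np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration axes."""
    acc = rec.acceleration if isinstance(rec, TimestampedRecording) else np.asarray(rec, float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValidationError("expected triaxial samples of shape (n, 3)")
    return np.linalg.norm(acc, axis=1)


def amplitude_percentiles(series: np.ndarray) -> np.ndarray:
    """Percentiles 30..70 (5% steps) of the series, linear interpolation."""
    x = np.asarray(series, dtype=float)
    if x.size < len(PERCENTILES):
        raise InsufficientDataError(
            f"need at least {len(PERCENTILES)} samples for percentiles"
        )
    return np.percentile(x, PERCENTILES)


def side_dominance(left: np.ndarray, right: np.ndarray) -> float:
    """Ratio of the 90th percentiles of the left and right series.

    The convention is fixed as left over right; swapping the arguments
    yields the reciprocal.  A non-positive right-side percentile is floored
    at 1e-6 g with a warning.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size == 0 or right.size == 0:
        raise InsufficientDataError("both series must be non-empty")
    p_left = float(np.percentile(left, 90))
    p_right = float(np.percentile(right, 90))
    if p_right <= _DOMINANCE_FLOOR:
        warnings.warn(
            "degenerate right-side 90th percentile; flooring denominator",
            stacklevel=2,
        )
        p_right = _DOMINANCE_FLOOR
    return p_left / p_right


def acceleration_sd(series: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the norm series."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 samples for a standard deviation")
    return float(np.std(x, ddof=1))


def _amplitude_spectrum(series: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    return freqs, spectrum


def fft_poly_features(
    rec: TimestampedRecording,
    degree: int = 3,
    band: tuple[float, float] = FFT_FIT_BAND,
    per_axis: bool = False,
) -> np.ndarray:
    """Degree-3 polynomial summary of the amplitude spectrum.

    The spectrum of the mean-removed norm series (or of each axis when
    ``per_axis``) over ``band`` is normalized to unit maximum and fitted by
    a least-squares polynomial in frequency.  The constant coefficient is
    dropped; the linear, quadratic and cubic coefficients are returned, so
    the output always has length ``degree`` (shape ``(3, degree)`` per
    axis).  A flat spectrum yields zeros with a warning.
    """
    rate = actual_sample_rate(rec.timestamps)
    if rec.duration < 2.0:
        raise InsufficientDataError("recording must span at least 2 s")

    def _fit(series: np.ndarray) -> np.ndarray:
        freqs, spec = _amplitude_spectrum(series, rate)
        mask = (freqs >= band[0]) & (freqs <= band[1])
        f, s = freqs[mask], spec[mask]
        peak = s.max() if s.size else 0.0
        if peak <= 0:
            warnings.warn("flat spectrum; returning zero coefficients", stacklevel=3)
            return np.zeros(degree)
        coeffs = np.polynomial.polynomial.polyfit(f, s / peak, degree)
        return coeffs[1:]  # drop the constant term

    if per_axis:
        return np.vstack([_fit(rec.acceleration[:, k]) for k in range(3)])
    return _fit(euclidean_norm(rec))


def symptom_count(answers) -> int:
    """Number of 'yes' answers on the non-motor-symptom questionnaire.

    Missing items (None/NaN) count as 'no' and are logged with a warning.
    """
    n_missing = 0
    count = 0
    for a in answers:
        if a is None or (isinstance(a, float) and np.isnan(a)):
            n_missing += 1
        elif bool(a):
            count += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} missing questionnaire answers treated as 'no'",
            stacklevel=2,
        )
    return count


# --------------------------------------------------------------------------
# feature table
# --------------------------------------------------------------------------

_QUESTIONNAIRE_FEATURES = {
    "age": "medical_history",
    "height": "medical_history",
    "weight": "medical_history",
    "family_history": "medical_history",
    "alcohol_effect": "medical_history",
    "nonmotor_yes_count": "symptoms",
}


def feature_schema(
    steps: tuple[str, ...] = EXAM_STEPS, wrists: tuple[str, ...] = WRISTS
) -> tuple[list[str], dict[str, str]]:
    """Ordered feature names and their group tags for a protocol."""
    names: list[str] = list(_QUESTIONNAIRE_FEATURES)
    groups: dict[str, str] = dict(_QUESTIONNAIRE_FEATURES)
    for step in steps:
        for wrist in wrists:
            prefix = f"s{step}_{wrist}"
            for p in PERCENTILES:
                names.append(f"{prefix}_p{p}")
                groups[f"{prefix}_p{p}"] = "amplitude_distribution"
            names.append(f"{prefix}_sd")
            groups[f"{prefix}_sd"] = "sd"
            for k in range(1, 4):
                names.append(f"{prefix}_fft_c{k}")
                groups[f"{prefix}_fft_c{k}"] = "fft"
        names.append(f"s{step}_dominance")
        groups[f"s{step}_dominance"] = "side_dominance"
    return names, groups


def _participant_row(exam: ExamRecordingSet) -> dict[str, float]:
    p = exam.participant
    row: dict[str, float] = {
        "age": p.age,
        "height": p.height,
        "weight": p.weight,
        "family_history": float(p.family_history),
        "alcohol_effect": float(p.alcohol_effect),
        "nonmotor_yes_count": float(symptom_count(p.nonmotor_answers)),
    }
    for step in EXAM_STEPS:
        demeaned: dict[str, np.ndarray | None] = {}
        for wrist in WRISTS:
            prefix = f"s{step}_{wrist}"
            rec = exam.recordings.get((step, wrist))
            if rec is None:
                demeaned[wrist] = None
                for p_ in PERCENTILES:
                    row[f"{prefix}_p{p_}"] = np.nan
                row[f"{prefix}_sd"] = np.nan
                for k in range(1, 4):
                    row[f"{prefix}_fft_c{k}"] = np.nan
                continue
            norm = euclidean_norm(rec)
            demeaned[wrist] = norm - norm.mean()
            for p_, v in zip(PERCENTILES, amplitude_percentiles(norm)):
                row[f"{prefix}_p{p_}"] = float(v)
            row[f"{prefix}_sd"] = acceleration_sd(norm)
            for k, c in enumerate(fft_poly_features(rec), start=1):
                row[f"{prefix}_fft_c{k}"] = float(c)
        if demeaned.get("left") is None or demeaned.get("right") is None:
            row[f"s{step}_dominance"] = np.nan
        else:
            row[f"s{step}_dominance"] = side_dominance(
                demeaned["left"], demeaned["right"]
            )
    return row


def build_feature_table(
    cohort: list[ExamRecordingSet],
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the per-participant feature table and label vector.

    Returns a DataFrame with one row per participant (indexed by
    participant id) over the full feature schema, plus the label Series.
    Features of missing recordings are imputed with the cohort median and
    logged; with a single participant the imputation is skipped with a
    warning.  Medication is deliberately not a feature.
    """
    if not cohort:
        raise ValidationError("cohort must contain at least one participant")
    names, _ = feature_schema()
    rows = []
    index = []
    labels = []
    for exam in cohort:
        # relaxed: tolerate missing recordings on ingested (non-synthetic) data
        rows.append(_participant_row(exam))
        index.append(exam.participant.participant_id)
        labels.append(exam.participant.label)
    table = pd.DataFrame(rows, index=index, columns=names)
    if table.isna().any().any():
        if len(table) < 2:
            warnings.warn(
                "missing features cannot be median-imputed in a cohort of one",
                stacklevel=2,
            )
        else:
            n_missing = int(table.isna().sum().sum())
            warnings.warn(
                f"imputing {n_missing} missing feature values with cohort medians",
                stacklevel=2,
            )
            table = table.fillna(table.median())
    return table, pd.Series(labels, index=index, name="label")
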