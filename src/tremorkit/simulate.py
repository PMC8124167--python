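"""Synthetic shaker campaigns and examination cohorts.

Everything downstream of this module (metrology, feature extraction,
classification) is exercised on data produced here, so the generators encode
the statistical structure those stages assume:

* **Shaker campaign** -- a vertical shaker table drives an ideal reference
  instrument and one or more imperfect watches with a constant-frequency,
  constant-amplitude sinusoid.  Watch imperfections are a sample-rate
  deficit, timestamp jitter, white self-noise, a constant zero-g offset and
  a multiplicative gain error that switches on above an amplitude threshold.
* **Examination cohort** -- labeled participants (Parkinson's disease "PD",
  differential diagnoses "DD", healthy) perform an 11-step, two-wrist
  examination protocol.  Each class has a tremor phenotype (frequency band,
  amplitude distribution, step-dependent modulation, left/right asymmetry)
  and class-dependent questionnaire answer probabilities.

Determinism contract: every public generator takes an integer ``seed`` and
produces byte-identical output for identical arguments.  Child random
streams are derived with :class:`numpy.random.SeedSequence` spawning, so the
outputs for participant *i* do not depend on how many participants precede
it only on the seed and its position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .recordings import STANDARD_GRAVITY, ReferenceRecording, TimestampedRecording

__all__ = [
    "SERIES_3",
    "SERIES_4",
    "IDEAL_WATCH",
    "ExamRecordingSet",
    "Participant",
    "SensorModel",
    "ShakerMeasurement",
    "StepPhenotype",
    "default_protocol",
    "default_sensor_models",
    "generate_cohort",
    "generate_examination",
    "generate_noise_study",
    "generate_shaker_campaign",
    "EXAM_STEPS",
    "STEP_DURATIONS",
    "WRISTS",
]


# --------------------------------------------------------------------------
# sensor models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    """Imperfection model of one watch accelerometer.

    Parameters
    ----------
    nominal_rate
        Officially specified sampling rate (Hz).
    actual_rate
        True sampling rate (Hz); consumer watches run up to 0.6 Hz short of
        the 100 Hz specification.
    timestamp_jitter_sd
        SD (s) of the read-out scatter added to interior timestamps.  The
        first and last stamps anchor the record, so jitter models clock
        read-out noise without biasing the timestamp-derived mean rate.
    noise_rms
        White self-noise RMS per axis (g).
    zero_g_offset
        Constant bias added to every axis (g).
    gain_error
        Multiplicative amplitude factor applied when the driven amplitude
        exceeds ``gain_error_onset``.
    gain_error_onset
        Amplitude threshold (g) above which the gain error applies.
    """

    name: str
    nominal_rate: float = 100.0
    actual_rate: float = 100.0
    timestamp_jitter_sd: float = 0.0
    noise_rms: float = 0.0
    zero_g_offset: float = 0.0
    gain_error: float = 1.0
    gain_error_onset: float = 0.05

    def __post_init__(self) -> None:
        if not self.actual_rate > 0:
            raise ValidationError("actual_rate must be positive")
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be positive")
        if self.noise_rms < 0:
            raise ValidationError("noise_rms must be non-negative")
        if self.timestamp_jitter_sd < 0:
            raise ValidationError("timestamp_jitter_sd must be non-negative")
        if not self.gain_error > 0:
            raise ValidationError("gain_error must be positive")


#: Series-3-like default watch model.
SERIES_3 = SensorModel(
    name="series3",
    actual_rate=99.6,
    timestamp_jitter_sd=0.5e-3,
    noise_rms=5e-4,
    zero_g_offset=1e-4,
    gain_error=1.03,
    gain_error_onset=0.05,
)

#: Series-4-like default watch model (slightly higher self-noise).
SERIES_4 = SensorModel(
    name="series4",
    actual_rate=99.4,
    timestamp_jitter_sd=0.5e-3,
    noise_rms=7e-4,
    zero_g_offset=1.5e-4,
    gain_error=1.04,
    gain_error_onset=0.05,
)

#: Perfect sensor: exact rate, no jitter, no noise, no offset, unit gain.
IDEAL_WATCH = SensorModel(name="ideal")


def default_sensor_models() -> list[SensorModel]:
    """The two default watch models used throughout the package."""
    return [SERIES_3, SERIES_4]


# --------------------------------------------------------------------------
# shaker campaign
# --------------------------------------------------------------------------

@dataclass
class ShakerMeasurement:
    """One paired (reference, watches) constant-tone shaker test."""

    measurement_id: str
    set_frequency: float  # Hz
    set_amplitude: float  # g
    duration: float  # s
    reference: ReferenceRecording
    watch_recordings: list[TimestampedRecording]

    def __post_init__(self) -> None:
        _validate_protocol_entry(self.set_frequency, self.set_amplitude)
        if not self.duration > 0:
            raise ValidationError("duration must be positive")

    @property
    def is_zero_vibration(self) -> bool:
        return self.set_frequency == 0


def _validate_protocol_entry(freq: float, amp: float) -> None:
    if freq < 0 or amp < 0:
        raise ValidationError("frequency and amplitude must be non-negative")
    if (freq == 0) != (amp == 0):
        raise ValidationError(
            "zero frequency and zero amplitude must occur together "
            "(the no-vibration test)"
        )
    if freq != 0 and not (3.0 <= freq <= 15.0):
        raise ValidationError("set frequency must be 0 or within [3, 15] Hz")
    if amp != 0 and not (0.002 <= amp <= 0.1):
        raise ValidationError("set amplitude must be 0 or within [0.002, 0.1] g")


def default_protocol() -> list[tuple[float, float]]:
    """Default 43-entry shaker protocol.

    A frequency sweep 3-15 Hz in 1 Hz steps at 0.01 g, an amplitude sweep
    at 5 Hz covering 0.002-0.1 g, repeats at two further constant
    frequencies with varied amplitude, and a single zero-vibration test.
    """
    protocol: list[tuple[float, float]] = [(0.0, 0.0)]
    protocol += [(float(f), 0.01) for f in range(3, 16)]  # 13 entries
    amp_sweep = [0.002, 0.004, 0.006, 0.008, 0.01, 0.02, 0.03, 0.04,
                 0.05, 0.06, 0.07, 0.08, 0.09, 0.1]  # 14 entries
    protocol += [(5.0, a) for a in amp_sweep]
    protocol += [(7.0, a) for a in [0.002, 0.005, 0.01, 0.02, 0.04, 0.06, 0.08, 0.1]]
    protocol += [(10.0, a) for a in [0.005, 0.01, 0.02, 0.04, 0.05, 0.06, 0.1]]
    assert len(protocol) == 43
    return protocol


def _watch_timestamps(model: SensorModel, n: int, rng: np.random.Generator) -> np.ndarray:
    stamps = np.arange(n) / model.actual_rate
    if model.timestamp_jitter_sd > 0 and n > 2:
        stamps = stamps.copy()
        stamps[1:-1] += rng.normal(0.0, model.timestamp_jitter_sd, n - 2)
        stamps = np.sort(stamps)  # jitter << sampling interval; keep monotone
    return stamps


def _simulate_watch(
    model: SensorModel,
    duration: float,
    rng: np.random.Generator,
    signal=None,
    **ids,
) -> TimestampedRecording:
    """Sample a (possibly None) triaxial signal with one watch model.

    ``signal`` is a callable mapping an array of true sample times to an
    ``(n, 3)`` acceleration array in g.  The ADC is treated as sampling
    uniformly at ``actual_rate``; the recorded timestamps carry read-out
    jitter on interior samples.
    """
    n = int(round(duration * model.actual_rate))
    true_times = np.arange(n) / model.actual_rate
    acc = np.zeros((n, 3))
    if signal is not None:
        acc += signal(true_times)
    if model.noise_rms > 0:
        acc += rng.normal(0.0, model.noise_rms, (n, 3))
    acc += model.zero_g_offset
    stamps = _watch_timestamps(model, n, rng)
    return TimestampedRecording(
        timestamps=stamps,
        acceleration=acc,
        nominal_rate=model.nominal_rate,
        device_id=ids.get("device_id", model.name),
        step_id=ids.get("step_id"),
        wrist=ids.get("wrist"),
    )


def _shaker_signal(model: SensorModel, freq: float, amp: float):
    if freq == 0:
        return None
    eff_amp = amp * model.gain_error if amp > model.gain_error_onset else amp
    omega = 2.0 * np.pi * freq

    def signal(t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        out[:, 2] = eff_amp * np.sin(omega * t)
        return out

    return signal


def _reference_recording(
    freq: float, amp: float, duration: float, rate: float, gain: float
) -> ReferenceRecording:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if freq == 0:
        counts = np.zeros(n)
    else:
        # a(t) = amp * g0 * sin(w t)  =>  v(t) = -(amp * g0 / w) cos(w t)
        omega = 2.0 * np.pi * freq
        v_m_s = -(amp * STANDARD_GRAVITY / omega) * np.cos(omega * t)
        counts = v_m_s * 1000.0 * gain  # m/s -> mm/s -> counts
    return ReferenceRecording(timestamps=t, velocity=counts, gain=gain, rate=rate)


def generate_shaker_campaign(
    protocol: list[tuple[float, float]] | None = None,
    sensor_models: list[SensorModel] | None = None,
    seed: int = 0,
    duration: float = 20.0,
    reference_rate: float = 100.0,
    reference_gain: float = 1200.0,
) -> list[ShakerMeasurement]:
    """Simulate a shaker campaign: one measurement per protocol entry.

    The reference stream is the exact analytic velocity of the driven
    sinusoid scaled by the instrument gain; each watch stream is the
    corresponding acceleration sampled through that watch's imperfection
    model.  With the default protocol this yields 43 measurements including
    exactly one zero-vibration test.
    """
    if protocol is None:
        protocol = default_protocol()
    if not protocol:
        raise ConfigurationError("protocol must contain at least one entry")
    if sensor_models is None:
        sensor_models = default_sensor_models()
    for freq, amp in protocol:
        _validate_protocol_entry(freq, amp)

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(protocol) * len(sensor_models))
    measurements = []
    for i, (freq, amp) in enumerate(protocol):
        watches = []
        for j, model in enumerate(sensor_models):
            rng = np.random.default_rng(children[i * len(sensor_models) + j])
            watches.append(
                _simulate_watch(
                    model, duration, rng, signal=_shaker_signal(model, freq, amp)
                )
            )
        measurements.append(
            ShakerMeasurement(
                measurement_id=f"M{i:03d}",
                set_frequency=float(freq),
                set_amplitude=float(amp),
                duration=duration,
                reference=_reference_recording(
                    freq, amp, duration, reference_rate, reference_gain
                ),
                watch_recordings=watches,
            )
        )
    return measurements


def generate_noise_study(
    n_per_model: int = 100,
    sensor_models: list[SensorModel] | None = None,
    seed: int = 0,
    duration: float = 20.0,
) -> list[TimestampedRecording]:
    """Generate repeated zero-vibration watch recordings for noise studies."""
    if n_per_model < 1:
        raise ConfigurationError("n_per_model must be at least 1")
    if sensor_models is None:
        sensor_models = default_sensor_models()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_per_model * len(sensor_models))
    recs = []
    k = 0
    for model in sensor_models:
        for _ in range(n_per_model):
            rng = np.random.default_rng(children[k])
            recs.append(_simulate_watch(model, duration, rng))
            k += 1
    return recs


# --------------------------------------------------------------------------
# examination cohort
# --------------------------------------------------------------------------

#: Examination steps and their durations in seconds.
STEP_DURATIONS: dict[str, float] = {
    "1a": 20.0,  # rest tremor, eyes closed
    "1b": 20.0,  # rest tremor under cognitive distraction (serial sevens)
    "2": 10.0,   # lift and extend arms
    "3": 10.0,   # remain arms lifted
    "4": 10.0,   # hold 1 kg weight
    "5": 10.0,   # finger pointing
    "6": 10.0,   # drink from glass
    "7": 10.0,   # cross and extend both arms
    "8": 10.0,   # index fingers to each other
    "9": 10.0,   # nose tapping
    "10": 20.0,  # entrainment by paced stomping, arms extended
}

EXAM_STEPS: tuple[str, ...] = tuple(STEP_DURATIONS)
WRISTS: tuple[str, str] = ("left", "right")

LABELS: tuple[str, ...] = ("PD", "DD", "healthy")

#: Table of (mean, SD) participant age per class, years.
AGE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "PD": (66.26, 9.61),
    "DD": (60.82, 12.87),
    "healthy": (61.45, 10.63),
}

#: Per-item probability of a "yes" non-motor-symptom answer, per class.
NONMOTOR_YES_P: dict[str, float] = {"PD": 0.40, "DD": 0.25, "healthy": 0.10}

N_NONMOTOR_ITEMS = 30

# Step-dependent amplitude modulation per class.  PD rest tremor grows under
# distraction (1b) and attenuates during action; DD action tremor dominates
# the posture/kinetic steps; healthy physiological tremor is uniform.
_PD_STEP_FACTOR = {"1a": 1.0, "1b": 1.5, **{s: 0.3 for s in EXAM_STEPS[2:]}}
_DD_STEP_FACTOR = {
    "1a": 0.2, "1b": 0.2, "2": 1.0, "3": 1.0, "4": 0.5,
    "5": 1.0, "6": 1.0, "7": 1.0, "8": 1.0, "9": 1.0, "10": 0.6,
}
_HEALTHY_STEP_FACTOR = {s: 1.0 for s in EXAM_STEPS}

#: Fraction of DD participants whose tremor entrains to the stomp pace.
DD_ENTRAINMENT_FRACTION = 0.3


@dataclass(frozen=True)
class StepPhenotype:
    """Tremor parameters of one (step, wrist) recording."""

    frequency: float  # Hz
    amplitude: float  # g


@dataclass
class Participant:
    """Labeled study participant with questionnaire and tremor phenotype."""

    participant_id: str
    label: str
    age: float
    height: float  # cm
    weight: float  # kg
    family_history: bool
    alcohol_effect: bool
    nonmotor_answers: list[bool]
    tremor_phenotype: dict[tuple[str, str], StepPhenotype] | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}")
        if not (30.0 <= self.age <= 90.0):
            raise ValidationError("age must lie within [30, 90] years")
        if len(self.nonmotor_answers) != N_NONMOTOR_ITEMS:
            raise ValidationError(
                f"nonmotor_answers must have {N_NONMOTOR_ITEMS} items"
            )


@dataclass
class ExamRecordingSet:
    """One participant's two-wrist examination.

    By default the set must contain exactly the 22 protocol recordings
    (11 steps x 2 wrists).  Ingested real-world data may be incomplete;
    pass ``require_complete=False`` to tolerate missing recordings (they
    surface as missing features downstream and are median-imputed).
    """

    participant: Participant
    recordings: dict[tuple[str, str], TimestampedRecording]
    require_complete: bool = True

    def __post_init__(self) -> None:
        expected = {(s, w) for s in EXAM_STEPS for w in WRISTS}
        extra = set(self.recordings) - expected
        if extra:
            raise ValidationError(f"unknown protocol recordings: {sorted(extra)}")
        missing = expected - set(self.recordings)
        if missing and self.require_complete:
            raise ValidationError(
                f"examination must contain exactly the 22 protocol recordings; "
                f"missing={sorted(missing)}"
            )


def _truncated_normal(rng, mean, sd, low, high) -> float:
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


#: Fraction of PD participants with an akinetic-rigid presentation (little
#: overt tremor) and of DD participants with a mixed rest/action tremor
#: (dystonic-like); both overlaps make the PD-vs-DD contrast genuinely
#: harder than the disease-vs-healthy contrasts, as in clinical practice.
PD_AKINETIC_FRACTION = 0.3
DD_MIXED_FRACTION = 0.4

#: SD of the per-step log-normal jitter on the amplitude modulation factors
#: (no two patients express the protocol identically).
STEP_FACTOR_JITTER_SD = 0.4


def _draw_phenotype(label: str, rng: np.random.Generator) -> dict:
    """Class-conditional tremor phenotype for all (step, wrist) pairs."""
    if label == "PD":
        freq = rng.uniform(4.0, 6.0)
        if rng.random() < PD_AKINETIC_FRACTION:
            # akinetic-rigid subtype: subtle tremor throughout
            base_amp = float(np.exp(rng.normal(np.log(0.003), 0.5)))
        else:
            base_amp = float(np.exp(rng.normal(np.log(0.02), 0.6)))
        asym = rng.uniform(2.0, 4.0)
        factors = dict(_PD_STEP_FACTOR)
    elif label == "DD":
        freq = rng.uniform(4.5, 8.0)
        base_amp = float(np.exp(rng.normal(np.log(0.02), 0.6)))
        asym = rng.uniform(1.0, 1.5)
        factors = dict(_DD_STEP_FACTOR)
        if rng.random() < DD_MIXED_FRACTION:
            factors["1a"] = factors["1b"] = 0.7  # rest component present
    else:
        freq = rng.uniform(8.0, 12.0)
        base_amp = rng.uniform(0.001, 0.0038)
        asym = rng.uniform(1.0, 1.3)
        factors = dict(_HEALTHY_STEP_FACTOR)

    if label != "healthy":
        for step in EXAM_STEPS:
            factors[step] *= float(
                np.exp(rng.normal(0.0, STEP_FACTOR_JITTER_SD))
            )

    dominant = WRISTS[int(rng.integers(2))]
    entrains = label == "DD" and rng.random() < DD_ENTRAINMENT_FRACTION
    stomp_pace = rng.uniform(1.5, 2.5)

    phenotype = {}
    for step in EXAM_STEPS:
        f_step = stomp_pace if (entrains and step == "10") else freq
        for wrist in WRISTS:
            amp = base_amp * factors[step]
            if wrist != dominant:
                amp /= asym
            phenotype[(step, wrist)] = StepPhenotype(frequency=f_step, amplitude=amp)
    return phenotype


def _draw_participant(label: str, pid: str, rng: np.random.Generator) -> Participant:
    mean, sd = AGE_DISTRIBUTIONS[label]
    age = _truncated_normal(rng, mean, sd, 30.0, 90.0)
    height = float(np.clip(rng.normal(171.0, 9.0), 150.0, 200.0))
    weight = float(np.clip(rng.normal(78.0, 14.0), 45.0, 130.0))
    family_p = {"PD": 0.20, "DD": 0.10, "healthy": 0.10}[label]
    alcohol_p = {"PD": 0.10, "DD": 0.50, "healthy": 0.05}[label]
    yes_p = NONMOTOR_YES_P[label]
    return Participant(
        participant_id=pid,
        label=label,
        age=age,
        height=height,
        weight=weight,
        family_history=bool(rng.random() < family_p),
        alcohol_effect=bool(rng.random() < alcohol_p),
        nonmotor_answers=[bool(v) for v in rng.random(N_NONMOTOR_ITEMS) < yes_p],
        tremor_phenotype=_draw_phenotype(label, rng),
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tremor_direction(rng: np.random.Generator, gravity: np.ndarray) -> np.ndarray:
    # wrist tremor is never orthogonal to gravity; keep a minimum projection
    # so the Euclidean-norm series retains the tremor fundamental
    for _ in range(64):
        u = _random_unit_vector(rng)
        if abs(float(u @ gravity)) >= 0.3:
            return u
    u = gravity.copy()
    return u


def generate_examination(
    participant: Participant,
    seed: int,
    sensor_models: tuple[SensorModel, SensorModel] = (SERIES_3, SERIES_4),
) -> ExamRecordingSet:
    """Simulate the 22 examination recordings of one participant.

    The signal of each recording is a constant gravity component (1 g along
    a random wrist orientation) plus a slowly amplitude-modulated tremor
    sinusoid along a random direction, passed through the wrist's watch
    sensor model (self-noise, offset, rate deficit, timestamp jitter).
    """
    if participant.tremor_phenotype is None:
        raise ValidationError("participant carries no tremor phenotype")
    for step in EXAM_STEPS:
        for wrist in WRISTS:
            if (step, wrist) not in participant.tremor_phenotype:
                raise ValidationError(
                    f"phenotype missing entry for step {step!r} wrist {wrist!r}"
                )
    unknown = set(participant.tremor_phenotype) - {
        (s, w) for s in EXAM_STEPS for w in WRISTS
    }
    if unknown:
        raise ValidationError(f"unknown step ids in phenotype: {sorted(unknown)}")

    root = np.random.SeedSequence(seed)
    wrist_models = dict(zip(WRISTS, sensor_models))
    orient_rng = np.random.default_rng(root.spawn(1)[0])
    gravity_dir = {w: _random_unit_vector(orient_rng) for w in WRISTS}

    children = iter(root.spawn(len(EXAM_STEPS) * len(WRISTS)))
    recordings = {}
    for step in EXAM_STEPS:
        for wrist in WRISTS:
            rng = np.random.default_rng(next(children))
            pheno = participant.tremor_phenotype[(step, wrist)]
            g_vec = gravity_dir[wrist]
            u = _tremor_direction(rng, g_vec)
            phase = rng.uniform(0, 2 * np.pi)
            mod_freq = rng.uniform(0.1, 0.4)
            mod_phase = rng.uniform(0, 2 * np.pi)
            omega = 2.0 * np.pi * pheno.frequency

            def signal(t, g_vec=g_vec, u=u, pheno=pheno, phase=phase,
                       mod_freq=mod_freq, mod_phase=mod_phase, omega=omega):
                envelope = pheno.amplitude * (
                    1.0 + 0.3 * np.sin(2 * np.pi * mod_freq * t + mod_phase)
                )
                tremor = envelope * np.sin(omega * t + phase)
                return g_vec[None, :] + u[None, :] * tremor[:, None]

            recordings[(step, wrist)] = _simulate_watch(
                wrist_models[wrist],
                STEP_DURATIONS[step],
                rng,
                signal=signal,
                device_id=wrist_models[wrist].name,
                step_id=step,
                wrist=wrist,
            )
    return ExamRecordingSet(participant=participant, recordings=recordings)


def generate_cohort(
    n_pd: int,
    n_dd: int,
    n_healthy: int,
    seed: int = 0,
    sensor_models: list[SensorModel] | None = None,
) -> list[ExamRecordingSet]:
    """Generate a labeled cohort with full examination recording sets.

    Watch models are assigned per participant by randomly ordering the two
    default models across the left and right wrist.
    """
    for name, n in (("n_pd", n_pd), ("n_dd", n_dd), ("n_healthy", n_healthy)):
        if n < 0:
            raise ValidationError(f"{name} must be non-negative")
    total = n_pd + n_dd + n_healthy
    if total == 0:
        raise ConfigurationError("cohort is empty: all class counts are zero")
    if sensor_models is None:
        sensor_models = default_sensor_models()
    if len(sensor_models) != 2:
        raise ConfigurationError("cohort generation expects exactly two watch models")

    labels = ["PD"] * n_pd + ["DD"] * n_dd + ["healthy"] * n_healthy
    root = np.random.SeedSequence(seed)
    children = root.spawn(total)
    cohort = []
    for i, label in enumerate(labels):
        ss = children[i]
        draw_ss, exam_ss = ss.spawn(2)
        rng = np.random.default_rng(draw_ss)
        participant = _draw_participant(label, f"P{i + 1:03d}", rng)
        order = (0, 1) if rng.random() < 0.5 else (1, 0)
        models = (sensor_models[order[0]], sensor_models[order[1]])
        exam_seed = int(exam_ss.generate_state(1)[0] % (2**31 - 1))
        cohort.append(generate_examination(participant, exam_seed, models))
    return cohort
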