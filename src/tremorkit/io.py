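"""Plain-CSV persistence for recordings, campaigns and cohorts.

One CSV per stream:

* watch recording: columns ``t_s, ax_g, ay_g, az_g``; cohort files are
  named ``P{id}_{step}_{wrist}.csv``;
* reference stream: columns ``t_s, v_counts``;
* campaign manifest ``campaign.csv``: one row per (measurement, device)
  with the set point, device name and stream file;
* cohort manifest ``cohort.csv``: one row per participant with label and
  questionnaire columns.

These formats are deliberately minimal -- they are the exchange dialect for
real-device ingestion as well, so readers tolerate missing recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .recordings import ReferenceRecording, TimestampedRecording
from .simulate import (
    EXAM_STEPS,
    N_NONMOTOR_ITEMS,
    WRISTS,
    ExamRecordingSet,
    Participant,
    ShakerMeasurement,
)

__all__ = [
    "read_campaign",
    "read_cohort",
    "read_recording_csv",
    "write_campaign",
    "write_cohort",
    "write_recording_csv",
]


def write_recording_csv(rec: TimestampedRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False)


def read_recording_csv(
    path,
    nominal_rate: float = 100.0,
    device_id: str = "watch",
    step_id: str | None = None,
    wrist: str | None = None,
) -> TimestampedRecording:
    df = pd.read_csv(path)
    required = {"t_s", "ax_g", "ay_g", "az_g"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"recording CSV must contain columns {sorted(required)}"
        )
    return TimestampedRecording(
        timestamps=df["t_s"].to_numpy(),
        acceleration=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
        nominal_rate=nominal_rate,
        device_id=device_id,
        step_id=step_id,
        wrist=wrist,
    )


# --------------------------------------------------------------------------
# shaker campaign
# --------------------------------------------------------------------------

def write_campaign(campaign: list[ShakerMeasurement], out_dir) -> Path:
    """Write a campaign to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in campaign:
        ref_file = f"{m.measurement_id}_reference.csv"
        pd.DataFrame(
            {"t_s": m.reference.timestamps, "v_counts": m.reference.velocity}
        ).to_csv(out / ref_file, index=False)
        rows.append(
            {
                "measurement_id": m.measurement_id,
                "set_freq_hz": m.set_frequency,
                "set_amp_g": m.set_amplitude,
                "device": "reference",
                "file": ref_file,
                "rate_hz": m.reference.rate,
                "gain": m.reference.gain,
            }
        )
        for rec in m.watch_recordings:
            f = f"{m.measurement_id}_{rec.device_id}.csv"
            write_recording_csv(rec, out / f)
            rows.append(
                {
                    "measurement_id": m.measurement_id,
                    "set_freq_hz": m.set_frequency,
                    "set_amp_g": m.set_amplitude,
                    "device": rec.device_id,
                    "file": f,
                    "rate_hz": rec.nominal_rate,
                    "gain": np.nan,
                }
            )
    manifest = out / "campaign.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_campaign(path) -> list[ShakerMeasurement]:
    """Read a campaign written by :func:`write_campaign`.

    ``path`` may be the manifest file or its directory.
    """
    path = Path(path)
    manifest = path if path.is_file() else path / "campaign.csv"
    base = manifest.parent
    df = pd.read_csv(manifest)
    measurements = []
    for mid, grp in df.groupby("measurement_id", sort=True):
        ref_rows = grp[grp["device"] == "reference"]
        if len(ref_rows) != 1:
            raise ValidationError(
                f"measurement {mid} must have exactly one reference stream"
            )
        ref_row = ref_rows.iloc[0]
        ref_df = pd.read_csv(base / ref_row["file"])
        reference = ReferenceRecording(
            timestamps=ref_df["t_s"].to_numpy(),
            velocity=ref_df["v_counts"].to_numpy(),
            gain=float(ref_row["gain"]),
            rate=float(ref_row["rate_hz"]),
        )
        watches = [
            read_recording_csv(
                base / row["file"],
                nominal_rate=float(row["rate_hz"]),
                device_id=str(row["device"]),
            )
            for _, row in grp[grp["device"] != "reference"].iterrows()
        ]
        duration = float(
            reference.timestamps[-1] - reference.timestamps[0]
        ) + 1.0 / reference.rate
        measurements.append(
            ShakerMeasurement(
                measurement_id=str(mid),
                set_frequency=float(ref_row["set_freq_hz"]),
                set_amplitude=float(ref_row["set_amp_g"]),
                duration=duration,
                reference=reference,
                watch_recordings=watches,
            )
        )
    return measurements


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def write_cohort(cohort: list[ExamRecordingSet], out_dir) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in cohort:
        p = exam.participant
        row = {
            "participant_id": p.participant_id,
            "label": p.label,
            "age": p.age,
            "height": p.height,
            "weight": p.weight,
            "family_history": int(p.family_history),
            "alcohol_effect": int(p.alcohol_effect),
        }
        for i, a in enumerate(p.nonmotor_answers, start=1):
            row[f"nm_{i:02d}"] = int(a)
        rows.append(row)
        for (step, wrist), rec in exam.recordings.items():
            write_recording_csv(
                rec, out / f"{p.participant_id}_{step}_{wrist}.csv"
            )
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(path, nominal_rate: float = 100.0) -> list[ExamRecordingSet]:
    """Read a cohort directory; missing recordings are tolerated."""
    path = Path(path)
    manifest = path if path.is_file() else path / "cohort.csv"
    base = manifest.parent
    df = pd.read_csv(manifest)
    cohort = []
    for _, row in df.iterrows():
        answers = [
            bool(row[f"nm_{i:02d}"]) for i in range(1, N_NONMOTOR_ITEMS + 1)
        ]
        participant = Participant(
            participant_id=str(row["participant_id"]),
            label=str(row["label"]),
            age=float(row["age"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            family_history=bool(row["family_history"]),
            alcohol_effect=bool(row["alcohol_effect"]),
            nonmotor_answers=answers,
            tremor_phenotype=None,
        )
        recordings = {}
        for step in EXAM_STEPS:
            for wrist in WRISTS:
                f = base / f"{participant.participant_id}_{step}_{wrist}.csv"
                if f.exists():
                    recordings[(step, wrist)] = read_recording_csv(
                        f,
                        nominal_rate=nominal_rate,
                        step_id=step,
                        wrist=wrist,
                    )
        cohort.append(
            ExamRecordingSet(
                participant=participant,
                recordings=recordings,
                require_complete=False,
            )
        )
    return cohort
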