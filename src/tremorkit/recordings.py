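"""Core recording containers.

Two kinds of streams flow through the package: triaxial smartwatch
acceleration with per-sample timestamps, and a single-axis reference
(seismometer-style) velocity stream expressed in digitizer counts.  Both are
thin dataclasses around NumPy arrays; all heavy processing lives in
:mod:`tremorkit.metrology`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Standard gravity used to express acceleration in multiples of g.
STANDARD_GRAVITY = 9.81  # m/s^2

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class TimestampedRecording:
    """One device's triaxial acceleration stream.

    Parameters
    ----------
    timestamps
        Per-sample timestamps in seconds, strictly increasing.
    acceleration
        Array of shape ``(n, 3)`` with acceleration in units of g
        (axes x, y, z).
    nominal_rate
        The officially specified sampling rate in Hz (the rate an analyst
        would assume without inspecting the timestamps).
    device_id, step_id, wrist
        Free-form identifiers used by the examination protocol and the
        campaign manifests.
    """

    timestamps: np.ndarray
    acceleration: np.ndarray
    nominal_rate: float
    device_id: str = "watch"
    step_id: str | None = None
    wrist: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        if self.acceleration.ndim != 2 or self.acceleration.shape[1] != 3:
            raise ValidationError(
                f"acceleration must have shape (n, 3), got {self.acceleration.shape}"
            )
        if self.timestamps.shape[0] != self.acceleration.shape[0]:
            raise ValidationError(
                "timestamps and acceleration must have the same length"
            )
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])

    def axis(self, name: str) -> np.ndarray:
        """Return one acceleration axis ('x', 'y' or 'z') as a 1-d array."""
        try:
            return self.acceleration[:, _AXES[name]]
        except KeyError:
            raise ValidationError(f"unknown axis {name!r}") from None

    @property
    def z(self) -> np.ndarray:
        return self.acceleration[:, 2]

    def to_frame(self) -> pd.DataFrame:
        """Recording as a DataFrame with columns ``t_s, ax_g, ay_g, az_g``."""
        return pd.DataFrame(
            {
                "t_s": self.timestamps,
                "ax_g": self.acceleration[:, 0],
                "ay_g": self.acceleration[:, 1],
                "az_g": self.acceleration[:, 2],
            }
        )


@dataclass
class ReferenceRecording:
    """Reference-instrument single-axis velocity stream.

    The stream is stored in raw digitizer counts together with the constant
    instrument gain (counts per mm/s).  Dividing by the gain recovers
    velocity in mm/s; the frequency-dependent instrument response is outside
    the scope of this package and is modelled as this single scalar.
    """

    timestamps: np.ndarray
    velocity: np.ndarray  # counts
    gain: float  # counts per (mm/s)
    rate: float  # Hz
    device_id: str = "reference"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 1:
            raise ValidationError("reference velocity must be 1-dimensional")
        if self.timestamps.shape != self.velocity.shape:
            raise ValidationError("timestamps and velocity must share a length")
        if not self.gain > 0:
            raise ValidationError("gain must be positive")
        if not self.rate > 0:
            raise ValidationError("rate must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def velocity_mm_s(self) -> np.ndarray:
        """Velocity in mm/s (counts divided by the instrument gain)."""
        return self.velocity / self.gain
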