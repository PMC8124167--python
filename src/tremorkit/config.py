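"""Run configuration: a single serializable object that, together with its
seed, reproduces a full study byte-identically."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .simulate import SensorModel, default_protocol, default_sensor_models


@dataclass
class RunConfig:
    """Parameters of a full simulation / validation / classification run."""

    seed: int = 1
    # shaker validation
    protocol: list | None = None  # None -> default 43-entry protocol
    sensor_models: list | None = None  # list of SensorModel kwargs dicts
    duration: float = 20.0
    reference_rate: float = 100.0
    reference_gain: float = 1200.0
    noise_recordings_per_model: int = 100
    # cohort
    n_pd: int = 260
    n_dd: int = 101
    n_healthy: int = 89
    # classification
    tasks: list = field(
        default_factory=lambda: ["pd_vs_healthy", "disease_vs_healthy", "pd_vs_dd"]
    )
    estimators: list = field(
        default_factory=lambda: ["svm_rbf", "boosted_trees", "mlp"]
    )
    n_outer: int = 5
    n_inner: int = 5
    importance_bootstraps: int = 100

    def __post_init__(self) -> None:
        checks = {
            "seed": isinstance(self.seed, int),
            "duration": self.duration > 0,
            "reference_rate": self.reference_rate > 0,
            "reference_gain": self.reference_gain > 0,
            "noise_recordings_per_model": self.noise_recordings_per_model >= 1,
            "n_pd": self.n_pd >= 0,
            "n_dd": self.n_dd >= 0,
            "n_healthy": self.n_healthy >= 0,
            "n_outer": self.n_outer >= 2,
            "n_inner": self.n_inner >= 2,
            "importance_bootstraps": self.importance_bootstraps >= 2,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigurationError(f"invalid configuration fields: {bad}")

    # -- resolved objects --------------------------------------------------

    def resolved_protocol(self) -> list[tuple[float, float]]:
        if self.protocol is None:
            return default_protocol()
        return [(float(f), float(a)) for f, a in self.protocol]

    def resolved_sensor_models(self) -> list[SensorModel]:
        if self.sensor_models is None:
            return default_sensor_models()
        return [SensorModel(**kw) for kw in self.sensor_models]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (including the seed)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
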