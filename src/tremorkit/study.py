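"""End-to-end study orchestration.

Two entry points tie the modules together:

* :func:`run_validation_study` -- simulate the shaker campaign and compare
  every watch against the reference (dominant frequency with and without
  sample-rate correction, oscillation amplitude, self-noise).
* :func:`run_classification_study` -- simulate the examination cohort,
  build the feature table, run every (task, estimator) nested CV and the
  bootstrap feature importance.

Every emitted artifact embeds the configuration hash, seed and package
version so a persisted config reproduces a run exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    BootstrapImportance,
    ClassificationResults,
    ImportanceResult,
    TremorClassifier,
)
from .config import RunConfig
from .features import build_feature_table, feature_schema
from .metrology import (
    actual_sample_rate,
    compare_measurement,
    noise_statistics,
)
from .simulate import generate_cohort, generate_noise_study, generate_shaker_campaign

logger = logging.getLogger("tremorkit")

__all__ = ["ValidationReport", "run_classification_study", "run_validation_study"]


@dataclass
class ValidationReport:
    """Wide per-measurement deviation table plus summary statistics."""

    table: pd.DataFrame  # one row per measurement (deviation or noise row)
    device_rows: pd.DataFrame  # long form, one row per (measurement, device)
    noise: pd.DataFrame  # per-device self-noise of the zero-vibration test
    summary: dict
    provenance: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def run_validation_study(
    config: RunConfig | None = None, campaign=None
) -> ValidationReport:
    """Simulate a shaker campaign and evaluate watch-vs-reference accuracy.

    The report table has one row per measurement: deviation rows for the
    vibrating tests (per-device columns) and one noise row for the
    zero-vibration test.  The summary collects the campaign-level envelope
    statistics (maximum deviations, noise levels, rate shortfall).  Pass a
    pre-built ``campaign`` (e.g. one read from disk) to analyse it instead
    of simulating.
    """
    if config is None:
        config = RunConfig()
    t0 = time.perf_counter()
    if campaign is None:
        campaign = generate_shaker_campaign(
            protocol=config.resolved_protocol(),
            sensor_models=config.resolved_sensor_models(),
            seed=config.seed,
            duration=config.duration,
            reference_rate=config.reference_rate,
            reference_gain=config.reference_gain,
        )
    logger.info("simulated %d measurements in %.1fs", len(campaign), time.perf_counter() - t0)

    long_rows = []
    noise_rows = []
    rate_shortfalls = []
    for m in campaign:
        if m.is_zero_vibration:
            for rec in m.watch_recordings:
                stats = noise_statistics(rec.z, actual_sample_rate(rec.timestamps))
                noise_rows.append(
                    {
                        "measurement_id": m.measurement_id,
                        "device": rec.device_id,
                        "rms_g": stats.rms,
                        "zero_g_offset_g": stats.zero_g_offset,
                    }
                )
            continue
        for rec in compare_measurement(m):
            long_rows.append(
                {
                    "measurement_id": m.measurement_id,
                    "set_freq_hz": rec.set_frequency,
                    "set_amp_g": rec.set_amplitude,
                    "device": rec.device_id,
                    "freq_ref_hz": rec.freq_ref,
                    "freq_watch_nominal_hz": rec.freq_watch_nominal,
                    "freq_watch_corrected_hz": rec.freq_watch_corrected,
                    "freq_dev_nominal_hz": rec.freq_deviation_nominal,
                    "freq_dev_corrected_hz": rec.freq_deviation_corrected,
                    "amp_ref_g": rec.amp_ref,
                    "amp_watch_g": rec.amp_watch,
                    "amp_dev_g": rec.amp_deviation,
                    "amp_ref_sd_g": rec.amp_ref_sd,
                    "amp_watch_sd_g": rec.amp_watch_sd,
                    "watch_rate_hz": rec.watch_rate,
                }
            )
        for rec in m.watch_recordings:
            rate_shortfalls.append(
                rec.nominal_rate - actual_sample_rate(rec.timestamps)
            )

    device_rows = pd.DataFrame(long_rows)
    noise = pd.DataFrame(noise_rows)

    wide = device_rows.pivot(
        index=["measurement_id", "set_freq_hz", "set_amp_g"],
        columns="device",
        values=[
            "freq_dev_nominal_hz",
            "freq_dev_corrected_hz",
            "amp_dev_g",
            "watch_rate_hz",
        ],
    )
    wide.columns = [f"{v}_{d}" for v, d in wide.columns]
    wide = wide.reset_index()
    if not noise.empty:
        noise_wide = {"measurement_id": noise["measurement_id"].iloc[0],
                      "set_freq_hz": 0.0, "set_amp_g": 0.0}
        for _, r in noise.iterrows():
            noise_wide[f"rms_g_{r['device']}"] = r["rms_g"]
            noise_wide[f"zero_g_offset_g_{r['device']}"] = r["zero_g_offset_g"]
        wide = pd.concat(
            [wide, pd.DataFrame([noise_wide])], ignore_index=True
        )

    small = device_rows[device_rows["set_amp_g"] <= 0.04]
    summary = {
        "n_measurements": len(campaign),
        "n_deviation_rows": int(device_rows["measurement_id"].nunique()),
        "max_abs_freq_dev_nominal_hz": float(
            device_rows["freq_dev_nominal_hz"].abs().max()
        ),
        "max_abs_freq_dev_corrected_hz": float(
            device_rows["freq_dev_corrected_hz"].abs().max()
        ),
        "mean_abs_freq_dev_corrected_hz": float(
            device_rows["freq_dev_corrected_hz"].abs().mean()
        ),
        "max_abs_amp_dev_g": float(device_rows["amp_dev_g"].abs().max()),
        "max_abs_amp_dev_le_0.04g_g": float(small["amp_dev_g"].abs().max())
        if not small.empty
        else float("nan"),
        "max_noise_rms_g": float(noise["rms_g"].max()) if not noise.empty else float("nan"),
        "max_abs_zero_g_offset_g": float(noise["zero_g_offset_g"].abs().max())
        if not noise.empty
        else float("nan"),
        "max_rate_shortfall_hz": float(np.max(rate_shortfalls))
        if rate_shortfalls
        else float("nan"),
    }
    logger.info("validation study complete in %.1fs", time.perf_counter() - t0)
    return ValidationReport(
        table=wide,
        device_rows=device_rows,
        noise=noise,
        summary=summary,
        provenance=_provenance(config),
    )


def run_classification_study(
    config: RunConfig | None = None, out_dir=None
) -> dict:
    """Simulate a cohort and run every configured (task, estimator) pair.

    Returns a dict with the feature table, one :class:`ClassificationResults`
    per (task, estimator), and the bootstrap importance for the
    disease-vs-healthy task.  When ``out_dir`` is given, one JSON result
    file per (task, estimator) plus an importance summary are written, each
    embedding the provenance block.
    """
    if config is None:
        config = RunConfig()
    t0 = time.perf_counter()
    cohort = generate_cohort(
        config.n_pd, config.n_dd, config.n_healthy, seed=config.seed
    )
    logger.info("generated cohort of %d in %.1fs", len(cohort), time.perf_counter() - t0)
    features, labels = build_feature_table(cohort)
    logger.info("feature table %s built in %.1fs", features.shape, time.perf_counter() - t0)

    provenance = _provenance(config)
    results: dict[tuple[str, str], ClassificationResults] = {}
    for task in config.tasks:
        for estimator in config.estimators:
            model = TremorClassifier(
                features,
                labels,
                task,
                estimator=estimator,
                n_outer=config.n_outer,
                n_inner=config.n_inner,
            )
            res = model.fit(seed=config.seed)
            results[(task, estimator)] = res
            logger.info(
                "%s/%s balanced accuracy %.3f (%.1fs)",
                task,
                estimator,
                res.mean()["balanced_accuracy"],
                time.perf_counter() - t0,
            )
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                payload = {"provenance": provenance, **res.to_dict()}
                (out / f"result_{task}_{estimator}.json").write_text(
                    json.dumps(payload, indent=2)
                )

    _, groups = feature_schema()
    importance = BootstrapImportance(
        features, labels, task="disease_vs_healthy", groups=groups
    ).fit(n_boot=config.importance_bootstraps, seed=config.seed)
    if out_dir is not None:
        out = Path(out_dir)
        payload = {
            "provenance": provenance,
            "group_medians": importance.group_medians().to_dict(),
        }
        (out / "importance_disease_vs_healthy.json").write_text(
            json.dumps(payload, indent=2)
        )
    logger.info("classification study complete in %.1fs", time.perf_counter() - t0)
    return {
        "features": features,
        "labels": labels,
        "results": results,
        "importance": importance,
        "provenance": provenance,
    }
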