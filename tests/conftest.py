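"""Shared fixtures: simulated campaigns, noise studies and cohorts.

Session-scoped fixtures keep the expensive simulations to a single run per
test session; everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from tremorkit.features import build_feature_table
from tremorkit.metrology import actual_sample_rate, compare_measurement
from tremorkit.simulate import (
    generate_cohort,
    generate_noise_study,
    generate_shaker_campaign,
)


@pytest.fixture(scope="session")
def default_campaign():
    """Default 43-measurement campaign with both default watch models."""
    return generate_shaker_campaign(seed=1)


@pytest.fixture(scope="session")
def campaign_deviations(default_campaign):
    """DeviationRecords of every vibrating measurement of the campaign."""
    records = []
    for m in default_campaign:
        if not m.is_zero_vibration:
            records.extend(compare_measurement(m))
    return records


@pytest.fixture(scope="session")
def campaign_rate_shortfalls(default_campaign):
    """Nominal-minus-actual sample rate of every watch recording."""
    out = []
    for m in default_campaign:
        for rec in m.watch_recordings:
            out.append(rec.nominal_rate - actual_sample_rate(rec.timestamps))
    return np.asarray(out)


@pytest.fixture(scope="session")
def noise_study():
    """100 zero-vibration 20 s recordings per default watch model."""
    return generate_noise_study(n_per_model=100, seed=2)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default examination cohort (260 PD / 101 DD / 89 healthy)."""
    return generate_cohort(260, 101, 89, seed=1)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature table and labels of the default cohort."""
    return build_feature_table(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort for feature-level tests."""
    return generate_cohort(3, 2, 2, seed=5)
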