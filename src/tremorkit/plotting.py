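"""Diagnostic plots mirroring the validation analyses.

All functions take a :class:`~tremorkit.study.ValidationReport` (or noise
statistics) and draw on a fresh or supplied Matplotlib axes, returning the
axes for further styling.  Importing this module requires matplotlib; the
rest of the package does not.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np


def plot_frequency_deviations(report, corrected: bool = True, ax=None):
    """Dominant-frequency deviation vs set frequency, one marker per device."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    col = "freq_dev_corrected_hz" if corrected else "freq_dev_nominal_hz"
    for device, grp in report.device_rows.groupby("device"):
        ax.plot(grp["set_freq_hz"], grp[col] * 1e3, "o", alpha=0.7, label=device)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("set frequency (Hz)")
    ax.set_ylabel("frequency deviation (mHz)")
    ax.set_title(
        "watch - reference dominant frequency"
        + (" (timestamp-corrected rate)" if corrected else " (nominal rate)")
    )
    ax.legend()
    return ax


def plot_amplitude_agreement(report, ax=None):
    """Watch amplitude against reference amplitude with SD error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for device, grp in report.device_rows.groupby("device"):
        ax.errorbar(
            grp["amp_ref_g"],
            grp["amp_watch_g"],
            xerr=grp["amp_ref_sd_g"],
            yerr=grp["amp_watch_sd_g"],
            fmt="o",
            ms=4,
            alpha=0.7,
            label=device,
        )
    lim = max(report.device_rows["amp_ref_g"].max(),
              report.device_rows["amp_watch_g"].max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("reference amplitude (g)")
    ax.set_ylabel("watch amplitude (g)")
    ax.set_title("oscillation amplitude agreement")
    ax.legend()
    return ax


def plot_noise_psd(noise_stats: dict, ax=None):
    """Power spectral densities of zero-vibration recordings.

    ``noise_stats`` maps a device label to a
    :class:`~tremorkit.metrology.NoiseStatistics`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, stats in noise_stats.items():
        mask = stats.psd_freq > 0
        ax.semilogy(stats.psd_freq[mask], stats.psd_power[mask], label=label)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"PSD (g$^2$/Hz)")
    ax.set_title("self-noise power spectral density")
    ax.legend()
    return ax
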