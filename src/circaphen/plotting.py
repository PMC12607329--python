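"""Minimal QC plots: diurnal profiles and group boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .timeseries import DiurnalProfile, PhaseSchedule


def plot_profile(
    profile: DiurnalProfile,
    schedule: PhaseSchedule | None = None,
    ax=None,
    label: str | None = None,
):
    """Mean +/- SEM diurnal profile with the dark phase shaded."""
    schedule = schedule or PhaseSchedule()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x, m, se = profile.bin_offsets, profile.means, profile.sems
    ax.plot(x, m, lw=1.5, label=label or profile.channel)
    ax.fill_between(x, m - se, m + se, alpha=0.3)
    if schedule.zt0_is_dark_onset:
        ax.axvspan(0, schedule.dark_hours, color="0.85", zorder=0)
    else:
        ax.axvspan(schedule.light_hours, schedule.period, color="0.85", zorder=0)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel(profile.channel)
    ax.set_xlim(0, schedule.period)
    return ax


def plot_group_box(values_by_group: dict[str, np.ndarray], ylabel: str = "", ax=None):
    """Boxplot per group with whiskers at 1.5 IQR and a marker at the mean."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    names = list(values_by_group)
    data = [np.asarray(values_by_group[g], float) for g in names]
    ax.boxplot(data, tick_labels=names, whis=1.5, showmeans=True)
    ax.set_ylabel(ylabel)
    return ax
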