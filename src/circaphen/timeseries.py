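"""Re-binning, light/dark annotation, phase averages and 24-h diurnal profiles.

Zeitgeber convention: recordings start at dark onset, so elapsed hour 0 is
ZT0 = lights-off and, with the default 14:10 schedule, hours [0, 10) of each
day are dark.  The common lights-on convention is expressible by setting
``zt0_is_dark_onset=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_phenomaster import (
    CUMULATIVE_CHANNELS,
    RATE_CHANNELS,
    RawChannelSeries,
    ValidationError,
)

Phase = Literal["dark", "light"]


@dataclass(frozen=True)
class PhaseSchedule:
    """The entraining light-dark cycle: period and phase durations in hours."""

    period: float = 24.0
    dark_hours: float = 10.0
    light_hours: float = 14.0
    zt0_is_dark_onset: bool = True

    def __post_init__(self):
        if self.dark_hours <= 0 or self.light_hours <= 0:
            raise ValueError("phase durations must be positive")
        if not np.isclose(self.dark_hours + self.light_hours, self.period):
            raise ValueError("dark_hours + light_hours must equal period")

    def phase_of(self, t) -> np.ndarray:
        """Phase label ('dark'/'light') for elapsed hour(s) t."""
        zt = np.asarray(t, dtype=float) % self.period
        first = self.dark_hours if self.zt0_is_dark_onset else self.light_hours
        in_first = zt < first
        if self.zt0_is_dark_onset:
            return np.where(in_first, "dark", "light")
        return np.where(in_first, "light", "dark")

    def phase_duration(self, phase: Phase) -> float:
        return self.dark_hours if phase == "dark" else self.light_hours

    def phase_intervals(self, t0: float, t1: float, phase: Phase) -> list[tuple[float, float]]:
        """Sub-intervals of [t0, t1] spent in ``phase``, as (start, end) hours."""
        if t1 <= t0:
            return []
        first = self.dark_hours if self.zt0_is_dark_onset else self.light_hours
        if (phase == "dark") == self.zt0_is_dark_onset:
            lo, hi = 0.0, first
        else:
            lo, hi = first, self.period
        out = []
        day = np.floor(t0 / self.period) * self.period
        while day < t1:
            a, b = max(t0, day + lo), min(t1, day + hi)
            if b > a:
                out.append((a, b))
            day += self.period
        return out


@dataclass(frozen=True)
class BinnedSeries:
    """A uniformly re-binned channel series with light/dark annotation.

    ``bin_start_times`` is the uniform grid tiling [0, T); ``bin_times`` holds
    the mean timestamp of the samples contributing to each bin (used as the
    regression abscissa downstream); missing bins carry NaN value and NaN
    bin_time.  ``phase_labels`` follow the schedule applied to bin starts.
    """

    animal_id: str
    group: str
    channel: str
    bin_width: float
    bin_start_times: np.ndarray
    bin_times: np.ndarray
    values: np.ndarray
    phase_labels: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.bin_start_times, dtype=float)
        if len(starts) > 1:
            dt = np.diff(starts)
            if not np.allclose(dt, self.bin_width, rtol=0, atol=1e-9):
                raise ValidationError("bin grid must be uniform with spacing bin_width")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of non-missing bins."""
        return np.isfinite(self.values)


@dataclass(frozen=True)
class DiurnalProfile:
    """Periodic (folded) average profile of one channel over [0, period)."""

    channel: str
    bin_offsets: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    n: np.ndarray


def bin_series(
    raw: RawChannelSeries,
    bin_width: float = 0.5,
    aggregator: Literal["auto", "mean", "sum"] = "auto",
    schedule: PhaseSchedule | None = None,
) -> BinnedSeries:
    """Aggregate a raw series into uniform bins tiling [0, T).

    ``aggregator='auto'`` picks mean for rate channels (vo2, vco2, rer) and
    sum for per-interval increments (feed, distance, activity).  Empty bins
    are flagged missing (NaN), never zero.
    """
    if len(raw) == 0:
        raise ValidationError("cannot bin an empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if aggregator == "auto":
        if raw.channel in RATE_CHANNELS:
            aggregator = "mean"
        elif raw.channel in CUMULATIVE_CHANNELS:
            aggregator = "sum"
        else:
            aggregator = "mean"
    schedule = schedule or PhaseSchedule()

    n_bins = int(np.floor(raw.times[-1] / bin_width)) + 1
    idx = np.floor(raw.times / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=raw.values, minlength=n_bins)
    tsums = np.bincount(idx, weights=raw.times, minlength=n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums if aggregator == "sum" else sums / counts
        values = np.where(counts > 0, values, np.nan)
        bin_times = np.where(counts > 0, tsums / np.maximum(counts, 1), np.nan)
    if not np.any(counts > 0):
        raise ValidationError("all bins empty")

    starts = np.arange(n_bins) * bin_width
    return BinnedSeries(
        raw.animal_id,
        raw.group,
        raw.channel,
        bin_width,
        starts,
        bin_times,
        values,
        schedule.phase_of(starts),
    )


def overall_average(binned: BinnedSeries) -> float:
    """Mean over all non-missing bins (the per-animal time-series average)."""
    ok = binned.present
    if not np.any(ok):
        raise ValidationError("no non-missing bins")
    return float(np.mean(binned.values[ok]))


def phase_average(binned: BinnedSeries, schedule: PhaseSchedule, phase: Phase) -> float:
    """Mean over non-missing bins whose start falls in the given phase."""
    labels = schedule.phase_of(binned.bin_start_times)
    ok = binned.present & (labels == phase)
    if not np.any(ok):
        raise ValidationError(f"no non-missing bins in phase {phase!r}")
    return float(np.mean(binned.values[ok]))


def periodic_average(
    binned: BinnedSeries,
    schedule: PhaseSchedule | None = None,
    complete_periods_only: bool = False,
) -> DiurnalProfile:
    """Fold a binned series across days into one representative daily profile.

    The value at offset o is the mean of bins with (bin_start mod period) == o;
    the SE is across the contributing days.  ``complete_periods_only`` drops
    bins beyond the last full period before folding.
    """
    schedule = schedule or PhaseSchedule()
    period = schedule.period
    n_per = int(round(period / binned.bin_width))
    if not np.isclose(n_per * binned.bin_width, period):
        raise ValidationError("bin_width must divide the period")
    if binned.bin_start_times[-1] + binned.bin_width < period:
        raise ValidationError("recording must span at least one full period")

    values = binned.values
    starts = binned.bin_start_times
    if complete_periods_only:
        n_full = int(np.floor((starts[-1] + binned.bin_width) / period))
        keep = starts < n_full * period
        values, starts = values[keep], starts[keep]

    slot = np.round((starts % period) / binned.bin_width).astype(int) % n_per
    means = np.full(n_per, np.nan)
    sems = np.full(n_per, np.nan)
    n = np.zeros(n_per, dtype=int)
    for k in range(n_per):
        v = values[slot == k]
        v = v[np.isfinite(v)]
        n[k] = len(v)
        if len(v):
            means[k] = v.mean()
            sems[k] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return DiurnalProfile(
        binned.channel, np.arange(n_per) * binned.bin_width, means, sems, n
    )


def pool_profiles(profiles: list[DiurnalProfile]) -> DiurnalProfile:
    """Across-animal mean profile with SEM over animals at each offset."""
    if not profiles:
        raise ValidationError("no profiles to pool")
    offsets = profiles[0].bin_offsets
    stack = np.vstack([p.means for p in profiles])
    n = np.sum(np.isfinite(stack), axis=0)
    means = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore"):
        sems = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return DiurnalProfile(profiles[0].channel, offsets, means, sems, n)
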