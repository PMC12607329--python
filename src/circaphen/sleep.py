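"""Sleep-architecture analysis from beam-break activity traces.

Rodent sleep in metabolic cages is scored behaviourally: a sleep bout is a
maximal run of consecutive zero-count activity epochs whose total duration
reaches a threshold (default 2 min at 10 s epochs — the cage system resolves
bouts of a few minutes).  Everything that is not sleep inside the analysis
window is wake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_phenomaster import RawChannelSeries, ValidationError
from .timeseries import Phase, PhaseSchedule


@dataclass(frozen=True)
class SleepBout:
    """One sleep bout: start (elapsed hours), duration (minutes), and the
    light/dark phase at its start."""

    start: float
    duration: float
    phase_at_start: str

    @property
    def end(self) -> float:
        """End time in elapsed hours."""
        return self.start + self.duration / 60.0


@dataclass(frozen=True)
class SleepArchitecture:
    """Per-animal sleep metrics over an analysis window.

    Percentages are of time asleep within the window / phase; episode counts
    assign each bout to its starting phase, while percentages split boundary-
    spanning bouts proportionally.  ``no_sleep``/``no_wake`` flag windows where
    a mean bout length is undefined (reported as 0).
    """

    animal_id: str
    bouts: tuple[SleepBout, ...]
    window: tuple[float, float]
    pct_sleep_total: float
    pct_sleep_light: float
    pct_sleep_dark: float
    episodes_per_hour: float
    mean_sleep_bout: float
    mean_wake_episode: float
    no_sleep: bool = False
    no_wake: bool = False


def detect_sleep_bouts(
    activity: RawChannelSeries,
    epoch: float = 10.0,
    min_sleep_duration: float = 2.0,
    merge_gap: float = 0.0,
    schedule: PhaseSchedule | None = None,
) -> list[SleepBout]:
    """Find maximal zero-activity runs of at least ``min_sleep_duration`` minutes.

    ``activity`` must sit on a uniform grid of ``epoch`` seconds (re-grid
    upstream otherwise).  ``merge_gap`` (minutes, default 0 = off) merges
    zero-runs separated by active gaps of at most that duration before
    thresholding, bridging single-epoch movement blips when requested.
    Bout boundaries are at epoch edges.
    """
    if min_sleep_duration <= 0:
        raise ValueError("min_sleep_duration must be positive")
    schedule = schedule or PhaseSchedule()
    t, v = activity.times, activity.values
    if len(t) == 0:
        return []
    epoch_h = epoch / 3600.0
    if len(t) > 1 and not np.allclose(np.diff(t), epoch_h, rtol=0, atol=1e-9):
        raise ValidationError(
            f"activity epochs are not uniform at {epoch} s; re-grid upstream"
        )
    if np.any(v < 0):
        raise ValidationError("activity counts must be non-negative")

    runs = _zero_runs(v == 0)
    if merge_gap > 0:
        runs = _merge_runs(runs, v, max_gap_epochs=int(round(merge_gap * 60 / epoch)))

    min_epochs = int(np.ceil(min_sleep_duration * 60.0 / epoch))
    bouts = []
    for i0, i1 in runs:  # half-open epoch index range [i0, i1)
        if i1 - i0 < min_epochs:
            continue
        start = t[0] + i0 * epoch_h
        duration_min = (i1 - i0) * epoch / 60.0
        bouts.append(
            SleepBout(float(start), float(duration_min), str(schedule.phase_of(start)))
        )
    return bouts


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index ranges."""
    padded = np.concatenate([[False], is_zero, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def _merge_runs(
    runs: list[tuple[int, int]], values: np.ndarray, max_gap_epochs: int
) -> list[tuple[int, int]]:
    if not runs or max_gap_epochs <= 0:
        return runs
    merged = [runs[0]]
    for i0, i1 in runs[1:]:
        p0, p1 = merged[-1]
        if i0 - p1 <= max_gap_epochs:
            merged[-1] = (p0, i1)
        else:
            merged.append((i0, i1))
    return merged


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def sleep_metrics(
    animal_id: str,
    bouts: list[SleepBout],
    window: tuple[float, float],
    schedule: PhaseSchedule | None = None,
) -> SleepArchitecture:
    """Summarise a bout list into sleep-architecture metrics for a window.

    Bout time is clipped to the window; time in each phase comes from exact
    interval intersections with the schedule's dark/light sub-intervals, so a
    bout spanning lights-on contributes to both phases proportionally.  Wake
    episodes are the maximal complements of the (clipped) sleep bouts.
    """
    schedule = schedule or PhaseSchedule()
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("empty analysis window")
    bouts = sorted(bouts, key=lambda b: b.start)

    clipped = []
    for b in bouts:
        a, z = max(b.start, t0), min(b.end, t1)
        if z > a:
            clipped.append((a, z))

    sleep_h = sum(z - a for a, z in clipped)
    phase_sleep = {}
    phase_time = {}
    for phase in ("dark", "light"):
        intervals = schedule.phase_intervals(t0, t1, phase)
        phase_time[phase] = sum(b - a for a, b in intervals)
        phase_sleep[phase] = sum(
            _overlap(a, z, p0, p1)
            for a, z in clipped
            for p0, p1 in intervals
        )

    # wake episodes: complement of sleep inside the window
    wake_eps = []
    cursor = t0
    for a, z in clipped:
        if a > cursor:
            wake_eps.append(a - cursor)
        cursor = max(cursor, z)
    if cursor < t1:
        wake_eps.append(t1 - cursor)

    window_h = t1 - t0
    n_bouts = len(clipped)
    pct = lambda s, tot: 100.0 * s / tot if tot > 0 else 0.0
    return SleepArchitecture(
        animal_id=animal_id,
        bouts=tuple(bouts),
        window=(t0, t1),
        pct_sleep_total=pct(sleep_h, window_h),
        pct_sleep_light=pct(phase_sleep["light"], phase_time["light"]),
        pct_sleep_dark=pct(phase_sleep["dark"], phase_time["dark"]),
        episodes_per_hour=n_bouts / window_h,
        mean_sleep_bout=(60.0 * sleep_h / n_bouts) if n_bouts else 0.0,
        mean_wake_episode=(60.0 * sum(wake_eps) / len(wake_eps)) if wake_eps else 0.0,
        no_sleep=n_bouts == 0,
        no_wake=len(wake_eps) == 0,
    )


def analyze_sleep(
    activity: RawChannelSeries,
    window: tuple[float, float] | None = None,
    epoch: float = 10.0,
    min_sleep_duration: float = 2.0,
    merge_gap: float = 0.0,
    schedule: PhaseSchedule | None = None,
) -> SleepArchitecture:
    """Convenience: detect bouts then summarise over the recording window."""
    schedule = schedule or PhaseSchedule()
    bouts = detect_sleep_bouts(activity, epoch, min_sleep_duration, merge_gap, schedule)
    if window is None:
        window = (float(activity.times[0]), float(activity.times[-1] + epoch / 3600.0))
    return sleep_metrics(activity.animal_id, bouts, window, schedule)
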