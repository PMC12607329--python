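"""Ingestion of metabolic-cage channel exports and small study tables.

The metabolic-cage reader consumes a documented delimited format (one row per
timestamp x animal, wide channel columns); a :class:`TableDialect` maps real
vendor exports onto it.  Timestamps are stored internally as elapsed decimal
hours with recording start = 0 = ZT0 (the recordings begin at dark onset), so
calendar parsing is confined to this module.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Physiological channels and their units.
#: vo2 / vco2: L/h/kg; feed: g/h; distance: m/h; activity: counts per epoch;
#: rer: dimensionless (derived, VCO2/VO2).
CHANNELS = ("vo2", "vco2", "feed", "distance", "activity", "rer")

#: Channels measured as instantaneous rates -> aggregated by mean when binned.
RATE_CHANNELS = frozenset({"vo2", "vco2", "rer"})

#: Channels measured as per-interval increments -> aggregated by sum.
CUMULATIVE_CHANNELS = frozenset({"feed", "distance", "activity"})

#: Channels that cannot physically be negative (balance resets clipped to 0).
NONNEGATIVE_CHANNELS = frozenset({"vo2", "vco2", "feed", "distance", "activity"})

DEFAULT_GROUPS = ("CNT", "IVF35", "IVF37")


class FormatError(ValueError):
    """Input table does not conform to the expected layout."""


class ValidationError(ValueError):
    """Input parsed but violates a data invariant (e.g. non-monotone time)."""


@dataclass(frozen=True)
class RawChannelSeries:
    """Timestamped measurements of one physiological channel for one animal.

    ``times`` are elapsed hours since recording start, strictly increasing;
    ``values`` are finite reals in channel units.
    """

    animal_id: str
    group: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValidationError("times and values must be 1-D and equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"non-monotone timestamps for animal {self.animal_id!r} "
                f"channel {self.channel!r}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("values must be finite")
        if self.channel == "activity" and np.any(values < 0):
            raise ValidationError("activity counts must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Recording span in hours (last minus first timestamp)."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass(frozen=True)
class GTTCurve:
    """Glucose-tolerance curve on a fixed minute grid; minute 0 is baseline."""

    animal_id: str
    minutes: np.ndarray
    glucose: np.ndarray
    group: str = ""

    #: The study's sampling grid: baseline then 15/30/60/120 min post bolus.
    STANDARD_MINUTES = (0.0, 15.0, 30.0, 60.0, 120.0)

    def __post_init__(self):
        minutes = np.asarray(self.minutes, dtype=float)
        glucose = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "minutes", minutes)
        object.__setattr__(self, "glucose", glucose)
        if len(minutes) != len(glucose):
            raise ValidationError("minutes and glucose must have equal length")
        if len(minutes) and minutes[0] != 0:
            raise ValidationError("first sample must be the minute-0 baseline")
        if np.any(np.diff(minutes) <= 0):
            raise ValidationError("minutes must be strictly increasing")
        if np.any(glucose <= 0):
            raise ValidationError("glucose must be positive")

    @property
    def baseline(self) -> float:
        return float(self.glucose[0])


@dataclass(frozen=True)
class MassRecord:
    """Body mass of one animal with its group label and littermate count.

    ``littermates`` enters group statistics as a continuous covariate because
    litter size confounds pre-weaning growth.
    """

    animal_id: str
    group: str
    littermates: int
    mass_3w: float
    mass_10w: float

    def __post_init__(self):
        if self.littermates < 1:
            raise ValidationError("littermates must be >= 1")
        if self.mass_3w <= 0 or self.mass_10w <= 0:
            raise ValidationError("masses must be positive")


@dataclass(frozen=True)
class TableDialect:
    """Column and format mapping for a delimited channel export.

    ``delimiter=None`` autodetects via :class:`csv.Sniffer` (TSV/CSV).
    ``time_format=None`` means the time column already holds elapsed decimal
    hours; otherwise it is a ``strptime`` pattern and ``recording_start``
    (same pattern, or the first timestamp when None) defines elapsed hour 0.
    ``channel_columns`` maps internal channel names to file column names.
    """

    delimiter: str | None = None
    animal_column: str = "animal_id"
    group_column: str | None = "group"
    time_column: str = "time_h"
    time_format: str | None = None
    recording_start: str | None = None
    channel_columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in CHANNELS if c != "rer"}
    )


@dataclass
class ReadResult:
    """Parsed series plus the count of rows dropped as unparseable."""

    series: list[RawChannelSeries]
    n_dropped: int

    def get(self, animal_id: str, channel: str) -> RawChannelSeries:
        for s in self.series:
            if s.animal_id == animal_id and s.channel == channel:
                return s
        raise KeyError((animal_id, channel))


def _numeric(col: pd.Series) -> pd.Series:
    """Parse strings to floats with correct rounding (bit-exact round trips);
    unparseable entries become NaN."""
    mask = pd.to_numeric(col, errors="coerce").notna()
    out = pd.Series(np.nan, index=col.index, dtype=float)
    if mask.any():
        out[mask] = col[mask].astype(float)
    return out


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_channel_table(path, dialect: TableDialect | None = None) -> ReadResult:
    """Read a wide delimited channel export into per-(animal, channel) series.

    Rows whose time or channel value fails to parse are dropped and counted.
    Negative feed/distance increments (hopper refills / balance resets) are
    clipped to 0 with a warning.

    Raises
    ------
    FormatError
        A mandatory column is missing (the message names it).
    ValidationError
        Timestamps for an animal are not strictly increasing.
    """
    dialect = dialect or TableDialect()
    sep = dialect.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")

    for col in (dialect.animal_column, dialect.time_column):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    present = {
        ch: col for ch, col in dialect.channel_columns.items() if col in df.columns
    }
    if not present:
        raise FormatError(
            f"no channel column found among {sorted(dialect.channel_columns.values())}"
        )

    if dialect.time_format is None:
        times = _numeric(df[dialect.time_column])
    else:
        stamps = pd.to_datetime(
            df[dialect.time_column], format=dialect.time_format, errors="coerce"
        )
        t0 = (
            datetime.strptime(dialect.recording_start, dialect.time_format)
            if dialect.recording_start
            else stamps.min()
        )
        times = (stamps - t0).dt.total_seconds() / 3600.0

    groups = (
        df[dialect.group_column]
        if dialect.group_column and dialect.group_column in df.columns
        else pd.Series([""] * len(df))
    )

    series: list[RawChannelSeries] = []
    n_dropped = 0
    for animal, idx in df.groupby(dialect.animal_column, sort=True).groups.items():
        t_all = times.loc[idx]
        group = str(groups.loc[idx].iloc[0]) if len(idx) else ""
        for channel, col in sorted(present.items()):
            vals = _numeric(df.loc[idx, col])
            ok = t_all.notna() & vals.notna()
            n_dropped += int((~ok).sum())
            t = t_all[ok].to_numpy(dtype=float)
            v = vals[ok].to_numpy(dtype=float)
            if len(t) == 0:
                continue
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"non-monotone timestamps for animal {animal!r}"
                )
            if channel in ("feed", "distance") and np.any(v < 0):
                warnings.warn(
                    f"{int((v < 0).sum())} negative {channel} increment(s) for "
                    f"animal {animal!r} clipped to 0 (balance reset)",
                    stacklevel=2,
                )
                v = np.clip(v, 0.0, None)
            series.append(
                RawChannelSeries(str(animal), group, channel, t, v)
            )
    return ReadResult(series, n_dropped)


def write_channel_table(
    series: Iterable[RawChannelSeries], path, delimiter: str = "\t"
) -> None:
    """Write series in the package's wide export format (read back losslessly
    by :func:`read_channel_table` with the default dialect).

    Channels sharing a time grid for an animal land on the same rows; float
    values are written with ``repr`` precision so a read round-trips
    bit-identically.
    """
    frames = [
        pd.DataFrame(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "time_h": s.times,
                "channel": s.channel,
                "value": s.values,
            }
        )
        for s in series
    ]
    if not frames:
        raise ValueError("no series to write")
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index=["animal_id", "group", "time_h"],
        columns="channel",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    wide = wide.sort_values(["animal_id", "time_h"], kind="stable")
    wide.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def compute_rer(vco2: RawChannelSeries, vo2: RawChannelSeries) -> RawChannelSeries:
    """Respiratory exchange ratio: elementwise VCO2/VO2 on the intersected grid.

    Points where VO2 <= 0 are dropped with a warning; an empty timestamp
    intersection is an error.
    """
    common, i1, i2 = np.intersect1d(vco2.times, vo2.times, return_indices=True)
    if len(common) == 0:
        raise ValidationError("vco2 and vo2 share no timestamps")
    num = vco2.values[i1]
    den = vo2.values[i2]
    ok = den > 0
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} point(s) with VO2 <= 0 dropped from RER",
            stacklevel=2,
        )
    return RawChannelSeries(
        vo2.animal_id, vo2.group, "rer", common[ok], num[ok] / den[ok]
    )


# -- small study tables -------------------------------------------------------

GTT_COLUMNS = ("animal_id", "group", "minute", "glucose")
MASS_COLUMNS = ("animal_id", "group", "littermates", "mass_3w", "mass_10w")


def read_gtt_table(path) -> list[GTTCurve]:
    """Read a long-format GTT CSV (columns: animal_id, group, minute, glucose)."""
    df = pd.read_csv(path)
    for col in GTT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    curves = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("minute")
        curves.append(
            GTTCurve(
                str(animal),
                sub["minute"].to_numpy(float),
                sub["glucose"].to_numpy(float),
                group=str(group),
            )
        )
    return curves


def read_mass_table(path) -> list[MassRecord]:
    """Read a body-mass CSV (columns: animal_id, group, littermates, mass_3w, mass_10w)."""
    df = pd.read_csv(path)
    for col in MASS_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return [
        MassRecord(
            str(r.animal_id), str(r.group), int(r.littermates),
            float(r.mass_3w), float(r.mass_10w),
        )
        for r in df.itertuples()
    ]


def write_gtt_table(curves: Sequence[GTTCurve], path) -> None:
    rows = [
        {"animal_id": c.animal_id, "group": c.group, "minute": m, "glucose": g}
        for c in curves
        for m, g in zip(c.minutes, c.glucose)
    ]
    pd.DataFrame(rows, columns=list(GTT_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_mass_table(records: Sequence[MassRecord], path) -> None:
    rows = [
        {
            "animal_id": r.animal_id, "group": r.group,
            "littermates": r.littermates,
            "mass_3w": r.mass_3w, "mass_10w": r.mass_10w,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MASS_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )
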