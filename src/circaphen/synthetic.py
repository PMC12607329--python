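"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a metabolic-cage phenotyping study of
three mouse groups (naturally conceived controls and two IVF groups cultured
at 35 or 37 degrees C for the first cleavage): 24-h cosine-shaped calorimetry
channels on a 14:10 light-dark cycle starting at dark onset, two-state
sleep/wake activity traces (alternating renewal with exponential bout
lengths), glucose-tolerance curves, litter-size-confounded body-mass tables,
and immunofluorescence field images of elliptical nuclei with known
per-nucleus mark/DAPI ratios.

Every generator is deterministic under the design seed (each output stream is
keyed by the design seed plus a stable hash of the entity identifiers) and
returns machine-readable ground truth sufficient to score the corresponding
estimator.  Default parameters mirror the study scale: groups of 7/10/10
animals, ~96 h of recording, 30-min analysis bins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_phenomaster import (
    GTTCurve,
    MassRecord,
    NONNEGATIVE_CHANNELS,
    RawChannelSeries,
)
from .histoquant import FieldImagePair
from .sleep import SleepBout
from .timeseries import PhaseSchedule


@dataclass(frozen=True)
class ChannelParams:
    """Cosine-rhythm parameters for one channel: mesor and amplitude in
    channel units, acrophase in hours after dark onset, additive Gaussian
    noise SD."""

    mesor: float
    amplitude: float
    acrophase: float
    noise_sd: float


@dataclass(frozen=True)
class SleepParams:
    """Alternating-renewal sleep/wake process, exponential bout lengths.

    Means are minutes; the long-run sleep fraction in a phase is
    sleep_mean / (sleep_mean + wake_mean).  ``wake_rate`` is the Poisson
    beam-break count per epoch while awake (must be > 0)."""

    light_sleep_mean: float = 7.0
    light_wake_mean: float = 3.0
    dark_sleep_mean: float = 3.0
    dark_wake_mean: float = 7.0
    wake_rate: float = 3.0

    def means(self, phase: str) -> tuple[float, float]:
        if phase == "light":
            return self.light_sleep_mean, self.light_wake_mean
        return self.dark_sleep_mean, self.dark_wake_mean


@dataclass(frozen=True)
class GTTParams:
    """Glucose excursion: baseline (mmol/L) plus a peak increment decaying
    exponentially from the 15-min sample; ``decay_tau_min = 0`` means the
    increment is sustained (no decay)."""

    baseline_mean: float = 5.5
    baseline_sd: float = 0.4
    peak_increment: float = 8.0
    decay_tau_min: float = 45.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class MassParams:
    """Linear mass model with litter-size confounding.

    mass = intercept + group_offset + slope * littermates + N(0, sd).
    Smaller IVF litters make the raw 3-week group means differ even when the
    direct group offsets are small — the confounding the covariate removes."""

    litter_mean: dict[str, float] = field(
        default_factory=lambda: {"CNT": 8.0, "IVF35": 5.0, "IVF37": 3.5}
    )
    intercept_3w: float = 16.0
    slope_3w: float = -0.45
    offsets_3w: dict[str, float] = field(
        default_factory=lambda: {"CNT": 0.0, "IVF35": 0.3, "IVF37": 0.4}
    )
    sd_3w: float = 1.0
    intercept_10w: float = 39.0
    slope_10w: float = -0.15
    offsets_10w: dict[str, float] = field(
        default_factory=lambda: {"CNT": 0.0, "IVF35": 2.5, "IVF37": 3.0}
    )
    sd_10w: float = 2.2


@dataclass(frozen=True)
class ImageParams:
    """Fields of elliptical nuclei on a noisy background (uint16 scale).

    Per-nucleus mark intensity is ratio_i x the DAPI pixel value inside the
    nucleus; ``ratio_means`` gives the group-level mean ratio per mark,
    ``ratio_sd`` the nucleus-to-nucleus spread.  Noise SD is a fraction of
    the DAPI dynamic range."""

    shape: tuple[int, int] = (512, 512)
    nuclei_per_field: int = 12
    radius_range: tuple[float, float] = (7.0, 11.0)
    background: float = 3000.0
    dapi_level_range: tuple[float, float] = (25000.0, 35000.0)
    mark_background: float = 1000.0
    ratio_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "H3K36me3": {"CNT": 1.30, "IVF35": 1.05, "IVF37": 1.00},
            "H3K27me3": {"CNT": 1.10, "IVF35": 1.08, "IVF37": 1.12},
            "H3K9me2": {"CNT": 1.20, "IVF35": 0.95, "IVF37": 1.18},
        }
    )
    ratio_sd: float = 0.05
    noise_sd_frac: float = 0.02
    min_separation: float = 10.0


def _default_channel_params() -> dict[str, dict[str, ChannelParams]]:
    """Per-group rhythm parameters echoing the study's qualitative findings:
    raised VO2 mesor at 35C, raised VO2 / lowered RER amplitude at 37C,
    raised feeding and locomotion in both IVF groups."""
    return {
        "CNT": {
            "vo2": ChannelParams(3.00, 0.50, 5.0, 0.15),
            "vco2": ChannelParams(2.70, 0.55, 5.0, 0.15),
            "feed": ChannelParams(0.15, 0.08, 4.0, 0.03),
            "distance": ChannelParams(20.0, 12.0, 5.0, 4.0),
        },
        "IVF35": {
            "vo2": ChannelParams(3.20, 0.55, 5.0, 0.15),
            "vco2": ChannelParams(2.88, 0.58, 5.0, 0.15),
            "feed": ChannelParams(0.16, 0.08, 4.0, 0.03),
            "distance": ChannelParams(26.0, 13.0, 5.0, 4.0),
        },
        "IVF37": {
            "vo2": ChannelParams(3.05, 0.70, 5.0, 0.15),
            "vco2": ChannelParams(2.75, 0.60, 5.0, 0.15),
            "feed": ChannelParams(0.18, 0.08, 4.0, 0.03),
            "distance": ChannelParams(26.0, 13.0, 5.0, 4.0),
        },
    }


def _default_sleep_params() -> dict[str, SleepParams]:
    return {
        "CNT": SleepParams(7.0, 3.0, 3.0, 7.0),
        "IVF35": SleepParams(6.0, 3.5, 2.8, 8.0),
        "IVF37": SleepParams(5.0, 4.5, 2.4, 9.5),
    }


@dataclass(frozen=True)
class SyntheticDesign:
    """Full parameterization of one synthetic study."""

    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (("CNT", 7), ("IVF35", 10), ("IVF37", 10))
    duration: float = 96.0          # hours of recording
    channel_interval: float = 0.1   # raw calorimetry sampling, hours (6 min)
    activity_epoch: float = 10.0    # seconds
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    channels: dict[str, dict[str, ChannelParams]] = field(
        default_factory=_default_channel_params
    )
    sleep: dict[str, SleepParams] = field(default_factory=_default_sleep_params)
    gtt: GTTParams = field(default_factory=GTTParams)
    mass: MassParams = field(default_factory=MassParams)
    image: ImageParams = field(default_factory=ImageParams)

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs, e.g. CNT_01 ... IVF37_10."""
        out = []
        for name, n in self.groups:
            out += [(f"{name}_{i + 1:02d}", name) for i in range(n)]
        return out

    def group_of(self, animal_id: str) -> str:
        for aid, g in self.animals():
            if aid == animal_id:
                return g
        raise KeyError(animal_id)


def _rng(design: SyntheticDesign, *tags) -> np.random.Generator:
    """Independent, reproducible stream keyed by the design seed and tags."""
    key = zlib.crc32("|".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence([design.seed, key]))


def gen_channel_series(
    design: SyntheticDesign,
    animal_id: str,
    channel: str,
    duration: float | None = None,
    sample_interval: float | None = None,
    noise_sd: float | None = None,
) -> RawChannelSeries:
    """Cosine rhythm plus Gaussian noise, clipped at 0 for physical channels."""
    group = design.group_of(animal_id)
    p = design.channels[group][channel]
    duration = design.duration if duration is None else duration
    dt = design.channel_interval if sample_interval is None else sample_interval
    sd = p.noise_sd if noise_sd is None else noise_sd
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    values = p.mesor + p.amplitude * np.cos(2 * np.pi * (t - p.acrophase) / 24.0)
    if sd > 0:
        values = values + _rng(design, "channel", animal_id, channel).normal(0, sd, n)
    if channel in NONNEGATIVE_CHANNELS:
        values = np.clip(values, 0.0, None)
    return RawChannelSeries(animal_id, group, channel, t, values)


def gen_activity_trace(
    design: SyntheticDesign,
    animal_id: str,
    duration: float | None = None,
    epoch: float | None = None,
) -> tuple[RawChannelSeries, list[SleepBout]]:
    """Alternating-renewal sleep/wake activity trace plus the planted bouts.

    Bout durations are exponential with phase-dependent means (phase taken at
    bout start), discretized to whole epochs (at least one).  Sleep epochs
    emit zero counts; wake epochs emit Poisson(wake_rate) counts, re-drawn
    until positive for the first epoch of each wake bout so that planted
    sleep bouts are exactly the maximal zero runs up to chance zero-count
    wake epochs elsewhere."""
    group = design.group_of(animal_id)
    p = design.sleep[group]
    duration = design.duration if duration is None else duration
    epoch = design.activity_epoch if epoch is None else epoch
    epoch_h = epoch / 3600.0
    n = int(round(duration * 3600.0 / epoch))
    rng = _rng(design, "activity", animal_id)

    counts = np.zeros(n, dtype=float)
    bouts: list[SleepBout] = []
    i = 0
    asleep = rng.random() < 0.5
    while i < n:
        t_start = i * epoch_h
        phase = str(design.schedule.phase_of(t_start))
        sleep_mean, wake_mean = p.means(phase)
        mean_min = sleep_mean if asleep else wake_mean
        n_ep = max(1, int(np.ceil(rng.exponential(mean_min) * 60.0 / epoch)))
        n_ep = min(n_ep, n - i)
        if asleep:
            bouts.append(SleepBout(t_start, n_ep * epoch / 60.0, phase))
        else:
            c = rng.poisson(p.wake_rate, n_ep)
            c[0] = max(c[0], 1)  # keep the run boundary crisp
            counts[i : i + n_ep] = c
        i += n_ep
        asleep = not asleep
    times = np.arange(n) * epoch_h
    return RawChannelSeries(animal_id, group, "activity", times, counts), bouts


def gen_gtt(
    design: SyntheticDesign, animal_id: str, noise: bool = True
) -> tuple[GTTCurve, dict]:
    """GTT curve on the standard minute grid, with its noiseless truth."""
    group = design.group_of(animal_id)
    p = design.gtt
    rng = _rng(design, "gtt", animal_id)
    minutes = np.array(GTTCurve.STANDARD_MINUTES)
    baseline = p.baseline_mean + (rng.normal(0, p.baseline_sd) if noise else 0.0)
    incr = np.zeros_like(minutes)
    post = minutes >= 15
    if p.decay_tau_min > 0:
        incr[post] = p.peak_increment * np.exp(-(minutes[post] - 15.0) / p.decay_tau_min)
    else:
        incr[post] = p.peak_increment
    glucose = baseline + incr
    truth_auc = float(np.trapezoid(incr, minutes))
    if noise and p.noise_sd > 0:
        jitter = rng.normal(0, p.noise_sd, len(minutes))
        jitter[0] = 0.0  # baseline defines the reference point
        glucose = glucose + jitter
    glucose = np.clip(glucose, 0.5, None)
    curve = GTTCurve(animal_id, minutes, glucose, group=group)
    return curve, {"baseline": float(baseline), "auc_noiseless": truth_auc}


def gen_mass_table(design: SyntheticDesign) -> tuple[list[MassRecord], dict]:
    """Body-mass records with litter-size confounding, plus the generative
    coefficients as truth."""
    p = design.mass
    rng = _rng(design, "mass")
    records = []
    for animal_id, group in design.animals():
        litter = max(1, int(rng.poisson(p.litter_mean[group])))
        m3 = (
            p.intercept_3w + p.offsets_3w[group] + p.slope_3w * litter
            + rng.normal(0, p.sd_3w)
        )
        m10 = (
            p.intercept_10w + p.offsets_10w[group] + p.slope_10w * litter
            + rng.normal(0, p.sd_10w)
        )
        records.append(
            MassRecord(animal_id, group, litter, max(m3, 1.0), max(m10, 1.0))
        )
    truth = {
        "offsets_3w": dict(p.offsets_3w),
        "offsets_10w": dict(p.offsets_10w),
        "slope_3w": p.slope_3w,
        "slope_10w": p.slope_10w,
    }
    return records, truth


@dataclass(frozen=True)
class ImageTruth:
    """Planted nuclei of one field: centers (row, col), semi-axes, orientation,
    DAPI level above background, and mark/DAPI ratio per nucleus."""

    centers: np.ndarray
    axes: np.ndarray
    angles: np.ndarray
    dapi_levels: np.ndarray
    ratios: np.ndarray


def gen_image_pair(
    design: SyntheticDesign,
    animal_id: str,
    field_id: str,
    mark_name: str,
    max_tries: int = 500,
) -> tuple[FieldImagePair, ImageTruth]:
    """One DAPI + mark field with non-overlapping elliptical nuclei.

    Inside nucleus i the noiseless mark equals ratio_i x the noiseless DAPI;
    both channels then get Gaussian noise (SD = noise_sd_frac of the DAPI
    dynamic range) and are quantized to uint16.  Placement is rejection
    sampling with a minimum center separation; exhaustion raises with a hint
    to request fewer nuclei."""
    group = design.group_of(animal_id)
    p = design.image
    rng = _rng(design, "image", animal_id, field_id, mark_name)
    h, w = p.shape
    rmax = p.radius_range[1]
    margin = rmax + 2

    centers = []
    min_d = 2 * rmax + p.min_separation
    tries = 0
    while len(centers) < p.nuclei_per_field:
        if tries > max_tries * p.nuclei_per_field:
            raise RuntimeError(
                "could not place non-overlapping nuclei; request fewer nuclei "
                "per field or a larger frame"
            )
        tries += 1
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(c - np.asarray(o))) >= min_d for o in centers):
            centers.append(c)
    centers = np.array(centers)

    n = len(centers)
    axes = rng.uniform(p.radius_range[0], p.radius_range[1], size=(n, 2))
    angles = rng.uniform(0, np.pi, size=n)
    dapi_levels = rng.uniform(*p.dapi_level_range, size=n)
    ratios = np.maximum(
        rng.normal(p.ratio_means[mark_name][group], p.ratio_sd, size=n), 0.1
    )

    rows, cols = np.mgrid[0:h, 0:w]
    dapi = np.full((h, w), p.background, dtype=float)
    mark = np.full((h, w), p.mark_background, dtype=float)
    for (cy, cx), (a, b), th, lev, r in zip(centers, axes, angles, dapi_levels, ratios):
        y0, y1 = int(max(0, cy - rmax - 1)), int(min(h, cy + rmax + 2))
        x0, x1 = int(max(0, cx - rmax - 1)), int(min(w, cx + rmax + 2))
        yy = rows[y0:y1, x0:x1] - cy
        xx = cols[y0:y1, x0:x1] - cx
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        patch_d = dapi[y0:y1, x0:x1]
        patch_m = mark[y0:y1, x0:x1]
        patch_d[inside] = p.background + lev
        patch_m[inside] = r * (p.background + lev)

    noise_sd = p.noise_sd_frac * (p.dapi_level_range[1])
    dapi += rng.normal(0, noise_sd, dapi.shape)
    mark += rng.normal(0, noise_sd, mark.shape)
    to_u16 = lambda img: np.clip(np.round(img), 0, 65535).astype(np.uint16)
    pair = FieldImagePair(
        animal_id, field_id, to_u16(dapi), to_u16(mark), mark_name, group=group
    )
    return pair, ImageTruth(centers, axes, angles, dapi_levels, ratios)


# -- dataset writer -----------------------------------------------------------

def write_dataset(
    design: SyntheticDesign,
    outdir,
    channels: tuple[str, ...] = ("vo2", "vco2", "feed", "distance"),
    n_fields_per_mark: int = 2,
    marks: tuple[str, ...] = ("H3K36me3",),
    with_images: bool = True,
) -> dict:
    """Write a complete synthetic study to ``outdir`` and return the truth.

    Produces ``channels.tsv`` (wide calorimetry export), ``activity.tsv``,
    ``gtt.csv``, ``mass.csv``, per-field TIFF pairs with ``fields.csv``
    manifest, and ``truth.json``."""
    import json

    import tifffile

    from .io_phenomaster import (
        write_channel_table,
        write_gtt_table,
        write_mass_table,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    series = [
        gen_channel_series(design, aid, ch)
        for aid, _ in design.animals()
        for ch in channels
    ]
    write_channel_table(series, outdir / "channels.tsv")

    truth: dict = {
        "seed": design.seed,
        "channels": {
            g: {ch: asdict(p) for ch, p in chans.items()}
            for g, chans in design.channels.items()
        },
        "sleep_bouts": {},
        "gtt": {},
    }

    activity = []
    for aid, _ in design.animals():
        trace, bouts = gen_activity_trace(design, aid)
        activity.append(trace)
        truth["sleep_bouts"][aid] = [
            {"start": b.start, "duration": b.duration, "phase": b.phase_at_start}
            for b in bouts
        ]
    write_channel_table(activity, outdir / "activity.tsv")

    curves = []
    for aid, _ in design.animals():
        curve, t = gen_gtt(design, aid)
        curves.append(curve)
        truth["gtt"][aid] = t
    write_gtt_table(curves, outdir / "gtt.csv")

    records, mass_truth = gen_mass_table(design)
    write_mass_table(records, outdir / "mass.csv")
    truth["mass"] = mass_truth

    if with_images:
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        rows = []
        truth["images"] = {}
        for aid, group in design.animals():
            for mark in marks:
                for f in range(n_fields_per_mark):
                    fid = f"{aid}_{mark}_f{f + 1}"
                    pair, t = gen_image_pair(design, aid, fid, mark)
                    dapi_path = f"images/{fid}_dapi.tif"
                    mark_path = f"images/{fid}_mark.tif"
                    tifffile.imwrite(outdir / dapi_path, pair.dapi)
                    tifffile.imwrite(outdir / mark_path, pair.mark)
                    rows.append(
                        {
                            "animal_id": aid,
                            "group": group,
                            "field_id": fid,
                            "dapi_path": dapi_path,
                            "mark_path": mark_path,
                            "mark_name": mark,
                        }
                    )
                    truth["images"][fid] = {
                        "centers": t.centers.tolist(),
                        "ratios": t.ratios.tolist(),
                    }
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "fields.csv", index=False)

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
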