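"""End-to-end orchestration: ingest -> bin -> rhythms/sleep/profiles -> stats.

``run_pipeline`` consumes a :class:`RunConfig` (loadable from YAML), runs every
stage on a data directory laid out like the synthetic writer's output, and
emits tidy CSVs plus a reproducibility manifest.  Any stage failure aborts
with the stage name in the exception message.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cosinor import fit_cosinor
from .groupstats import ancova, gtt_auc, lsd_posthoc, mann_whitney
from .histoquant import aggregate_animal, quantify_field, read_manifest, segment_nuclei
from .io_phenomaster import (
    TableDialect,
    compute_rer,
    read_channel_table,
    read_gtt_table,
    read_mass_table,
)
from .sleep import analyze_sleep
from .timeseries import (
    PhaseSchedule,
    bin_series,
    overall_average,
    periodic_average,
    phase_average,
)

log = logging.getLogger("circaphen")

#: channels fitted on a log scale (skewed, zero-inflated behavioural channels)
DEFAULT_LOG_CHANNELS = ("feed", "distance")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see docs for the YAML schema)."""

    data_dir: str
    out_dir: str
    bin_width: float = 0.5
    period: float = 24.0
    dark_hours: float = 10.0
    light_hours: float = 14.0
    analysis_window: tuple[float, float] | None = None
    log_channels: tuple[str, ...] = DEFAULT_LOG_CHANNELS
    sleep_epoch: float = 10.0
    min_sleep_duration: float = 2.0
    merge_gap: float = 0.0
    histo_window: int = 61
    histo_open_iterations: int = 5
    histo_min_area: int = 50
    control_group: str = "CNT"
    seed: int = 0

    @property
    def schedule(self) -> PhaseSchedule:
        return PhaseSchedule(self.period, self.dark_hours, self.light_hours)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "analysis_window" in raw and raw["analysis_window"] is not None:
            raw["analysis_window"] = tuple(raw["analysis_window"])
        if "log_channels" in raw:
            raw["log_channels"] = tuple(raw["log_channels"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("ingest")
def _ingest(cfg: RunConfig):
    data = Path(cfg.data_dir)
    chan_path = data / "channels.tsv"
    if not chan_path.exists():
        raise FileNotFoundError(f"no channel table at {chan_path}")
    result = read_channel_table(chan_path, TableDialect())
    activity = None
    if (data / "activity.tsv").exists():
        activity = read_channel_table(
            data / "activity.tsv", TableDialect(channel_columns={"activity": "activity"})
        )
    gtt = read_gtt_table(data / "gtt.csv") if (data / "gtt.csv").exists() else []
    mass = read_mass_table(data / "mass.csv") if (data / "mass.csv").exists() else []
    return result, activity, gtt, mass


@_stage("rhythms")
def _rhythms(cfg: RunConfig, result):
    schedule = cfg.schedule
    by_animal: dict[str, dict] = {}
    for s in result.series:
        by_animal.setdefault(s.animal_id, {})[s.channel] = s
    for animal, chans in by_animal.items():
        if "vo2" in chans and "vco2" in chans:
            chans["rer"] = compute_rer(chans["vco2"], chans["vo2"])

    avg_rows, cos_rows, prof_rows = [], [], []
    for animal, chans in sorted(by_animal.items()):
        for channel, raw in sorted(chans.items()):
            if cfg.analysis_window is not None:
                t0, t1 = cfg.analysis_window
                keep = (raw.times >= t0) & (raw.times < t1)
                raw = type(raw)(
                    raw.animal_id, raw.group, raw.channel,
                    raw.times[keep] - t0, raw.values[keep],
                )
            binned = bin_series(raw, cfg.bin_width, schedule=schedule)
            fit = fit_cosinor(
                binned, cfg.period, log_transform=channel in cfg.log_channels
            )
            avg_rows.append(
                {
                    "animal_id": animal,
                    "group": raw.group,
                    "channel": channel,
                    "overall": overall_average(binned),
                    "dark": phase_average(binned, schedule, "dark"),
                    "light": phase_average(binned, schedule, "light"),
                }
            )
            cos_rows.append(
                {
                    "animal_id": animal,
                    "group": raw.group,
                    "channel": channel,
                    "mesor": fit.mesor,
                    "amplitude": fit.amplitude,
                    "acrophase": fit.acrophase,
                    "log_transformed": fit.log_transformed,
                    "degenerate": fit.degenerate,
                    "unreliable": fit.unreliable,
                }
            )
            prof = periodic_average(binned, schedule)
            for o, m, se, n in zip(prof.bin_offsets, prof.means, prof.sems, prof.n):
                prof_rows.append(
                    {
                        "animal_id": animal,
                        "group": raw.group,
                        "channel": channel,
                        "zt": o,
                        "mean": m,
                        "sem": se,
                        "n_days": n,
                    }
                )
    return pd.DataFrame(avg_rows), pd.DataFrame(cos_rows), pd.DataFrame(prof_rows)


@_stage("sleep")
def _sleep(cfg: RunConfig, activity_result):
    rows = []
    if activity_result is None:
        return pd.DataFrame(rows)
    for s in activity_result.series:
        arch = analyze_sleep(
            s,
            epoch=cfg.sleep_epoch,
            min_sleep_duration=cfg.min_sleep_duration,
            merge_gap=cfg.merge_gap,
            schedule=cfg.schedule,
        )
        rows.append(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "pct_sleep_total": arch.pct_sleep_total,
                "pct_sleep_light": arch.pct_sleep_light,
                "pct_sleep_dark": arch.pct_sleep_dark,
                "episodes_per_hour": arch.episodes_per_hour,
                "mean_sleep_bout": arch.mean_sleep_bout,
                "mean_wake_episode": arch.mean_wake_episode,
            }
        )
    return pd.DataFrame(rows)


@_stage("gtt")
def _gtt(curves):
    return pd.DataFrame(
        [
            {
                "animal_id": c.animal_id,
                "group": c.group,
                "baseline": c.baseline,
                "auc": gtt_auc(c),
            }
            for c in curves
        ]
    )


@_stage("histo")
def _histo(cfg: RunConfig, data_dir):
    manifest = Path(data_dir) / "fields.csv"
    if not manifest.exists():
        return pd.DataFrame(), pd.DataFrame()
    pairs = read_manifest(manifest)
    nuc_rows, summaries = [], {}
    for pair in pairs:
        seg = segment_nuclei(
            pair.dapi,
            window=cfg.histo_window,
            open_iterations=cfg.histo_open_iterations,
            min_area=cfg.histo_min_area,
        )
        records = quantify_field(pair, seg)
        key = (pair.animal_id, pair.mark_name, pair.group)
        summaries.setdefault(key, []).extend(records)
        for r in records:
            nuc_rows.append(
                {
                    "animal_id": pair.animal_id,
                    "group": pair.group,
                    "field_id": pair.field_id,
                    "mark": pair.mark_name,
                    "nucleus_id": r.nucleus_id,
                    "area": r.area,
                    "mean_dapi": r.mean_dapi,
                    "mean_mark": r.mean_mark,
                    "ratio": r.ratio,
                }
            )
    sum_rows = []
    for (animal, mark, group), recs in sorted(summaries.items()):
        if not recs:
            continue
        s = aggregate_animal(animal, mark, recs, group=group)
        sum_rows.append(
            {
                "animal_id": animal,
                "group": group,
                "mark": mark,
                "mean_ratio": s.mean_ratio,
                "n_nuclei": s.n_nuclei,
                "sd_ratio": s.sd_ratio,
            }
        )
    return pd.DataFrame(nuc_rows), pd.DataFrame(sum_rows)


@_stage("stats")
def _stats(cfg: RunConfig, mass, endpoint_frames: dict[str, pd.DataFrame]):
    rows = []
    if mass:
        for response in ("mass_3w", "mass_10w"):
            res = ancova(mass, response)
            rows.append(
                {
                    "endpoint": response,
                    "test": "ancova",
                    "term": "group",
                    "statistic": res.F_group,
                    "df": f"{res.df_group[0]},{res.df_group[1]}",
                    "p": res.p_group,
                }
            )
            rows.append(
                {
                    "endpoint": response,
                    "test": "ancova",
                    "term": "littermates",
                    "statistic": res.F_covariate,
                    "df": f"{res.df_covariate[0]},{res.df_covariate[1]}",
                    "p": res.p_covariate,
                }
            )
            for c in lsd_posthoc(res):
                rows.append(
                    {
                        "endpoint": response,
                        "test": "lsd",
                        "term": f"{c.group_a} vs {c.group_b}",
                        "statistic": c.t,
                        "df": str(c.df),
                        "p": c.p,
                    }
                )
    for name, frame in endpoint_frames.items():
        if frame.empty:
            continue
        value_cols = [
            c for c in frame.columns
            if c not in ("animal_id", "group", "channel", "mark", "field_id")
            and frame[c].dtype.kind in "fi"
        ]
        keys = [c for c in ("channel", "mark") if c in frame.columns]
        for key_vals, sub in frame.groupby(keys) if keys else [((), frame)]:
            label = ":".join(np.atleast_1d(key_vals).astype(str)) if keys else ""
            groups = sorted(sub["group"].unique())
            for col in value_cols:
                for ga_idx in range(len(groups)):
                    for gb_idx in range(ga_idx + 1, len(groups)):
                        ga, gb = groups[ga_idx], groups[gb_idx]
                        xa = sub.loc[sub["group"] == ga, col].to_numpy(float)
                        xb = sub.loc[sub["group"] == gb, col].to_numpy(float)
                        if len(xa) == 0 or len(xb) == 0:
                            continue
                        mw = mann_whitney(xa, xb)
                        rows.append(
                            {
                                "endpoint": f"{name}:{label}:{col}" if label else f"{name}:{col}",
                                "test": "mannwhitney",
                                "term": f"{ga} vs {gb}",
                                "statistic": mw.U,
                                "df": f"{mw.n1},{mw.n2}",
                                "p": mw.p,
                            }
                        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write tidy CSVs + run manifest under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result, activity, gtt_curves, mass = _ingest(cfg)
    averages, cosinor_df, profiles = _rhythms(cfg, result)
    sleep_df = _sleep(cfg, activity)
    gtt_df = _gtt(gtt_curves) if gtt_curves else pd.DataFrame()
    nuclei_df, histo_df = _histo(cfg, cfg.data_dir)
    stats_df = _stats(
        cfg,
        mass,
        {
            "average": averages,
            "cosinor": cosinor_df.drop(
                columns=["log_transformed", "degenerate", "unreliable"],
                errors="ignore",
            ),
            "sleep": sleep_df,
            "gtt": gtt_df,
            "histo": histo_df,
        },
    )

    frames = {
        "averages": averages,
        "cosinor": cosinor_df,
        "profiles": profiles,
        "sleep": sleep_df,
        "gtt": gtt_df,
        "nuclei": nuclei_df,
        "histo_summary": histo_df,
        "stats": stats_df,
    }
    for name, frame in frames.items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    manifest = {
        "package": "circaphen",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_dropped_rows": result.n_dropped,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return frames
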