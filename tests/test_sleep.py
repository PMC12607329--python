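import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

from circaphen import (
    PhaseSchedule,
    RawChannelSeries,
    SleepBout,
    detect_sleep_bouts,
    gen_activity_trace,
    sleep_metrics,
)
from circaphen.io_phenomaster import ValidationError
from circaphen.synthetic import SleepParams, SyntheticDesign
from oracles import interval_sleep_oracle, rle_sleep_oracle

EPOCH = 10.0
EPOCH_H = EPOCH / 3600.0


def _trace(counts):
    counts = np.asarray(counts, float)
    return RawChannelSeries(
        "m1", "CNT", "activity", np.arange(len(counts)) * EPOCH_H, counts
    )


class TestDetect:
    def test_all_zero_hour_is_one_60min_bout(self):
        bouts = detect_sleep_bouts(_trace(np.zeros(360)), EPOCH, 2.0)
        assert len(bouts) == 1
        assert bouts[0].start == 0.0
        assert bouts[0].duration == 60.0

    def test_alternating_epochs_yield_no_bouts(self):
        bouts = detect_sleep_bouts(_trace(np.tile([0, 1], 180)), EPOCH, 2.0)
        assert bouts == []

    def test_run_shorter_than_threshold_is_wake(self):
        counts = np.ones(100)
        counts[10:21] = 0  # 11 epochs = 110 s < 2 min
        assert detect_sleep_bouts(_trace(counts), EPOCH, 2.0) == []
        counts[10:22] = 0  # 12 epochs = exactly 2 min
        bouts = detect_sleep_bouts(_trace(counts), EPOCH, 2.0)
        assert len(bouts) == 1 and bouts[0].duration == 2.0

    def test_non_uniform_grid_is_error(self):
        s = RawChannelSeries("m1", "CNT", "activity", [0.0, 0.01, 0.5], [0, 0, 0])
        with pytest.raises(ValidationError, match="uniform"):
            detect_sleep_bouts(s, EPOCH, 2.0)

    def test_merge_gap_bridges_single_blips(self):
        counts = np.ones(100)
        counts[10:20] = 0
        counts[21:31] = 0  # single active epoch between two 100 s runs
        assert detect_sleep_bouts(_trace(counts), EPOCH, 2.0) == []
        merged = detect_sleep_bouts(_trace(counts), EPOCH, 2.0, merge_gap=10 / 60)
        assert len(merged) == 1

    @given(stn.lists(stn.integers(0, 2), min_size=1, max_size=400))
    @settings(max_examples=200, deadline=None)
    def test_matches_rle_oracle(self, counts):
        bouts = detect_sleep_bouts(_trace(counts), EPOCH, 2.0)
        expected = rle_sleep_oracle(counts, EPOCH, 2.0)
        assert len(bouts) == len(expected)
        for b, (i0, n) in zip(bouts, expected):
            assert np.isclose(b.start, i0 * EPOCH_H)
            assert np.isclose(b.duration, n * EPOCH / 60.0)

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never increases bout count or sleep time."""
        counts = (rng.random(2000) < 0.6).astype(float)
        prev_n, prev_t = np.inf, np.inf
        for thr in (0.5, 1.0, 2.0, 5.0):
            bouts = detect_sleep_bouts(_trace(counts), EPOCH, thr)
            total = sum(b.duration for b in bouts)
            assert len(bouts) <= prev_n and total <= prev_t
            prev_n, prev_t = len(bouts), total


class TestMetrics:
    def test_half_window_bout(self, schedule):
        bouts = [SleepBout(0.0, 12 * 60.0, "dark")]
        arch = sleep_metrics("m1", bouts, (0.0, 24.0), schedule)
        assert arch.pct_sleep_total == 50.0
        assert arch.episodes_per_hour == pytest.approx(1 / 24)
        assert arch.mean_sleep_bout == 12 * 60.0

    def test_empty_bout_list_flagged(self, schedule):
        arch = sleep_metrics("m1", [], (0.0, 24.0), schedule)
        assert arch.pct_sleep_total == 0.0
        assert arch.episodes_per_hour == 0.0
        assert arch.mean_sleep_bout == 0.0
        assert arch.no_sleep

    def test_boundary_spanning_bout_split_proportionally(self, schedule):
        # dark is [0, 10); a 9.5->10.5 h bout puts 30 min in each phase
        arch = sleep_metrics("m1", [SleepBout(9.5, 60.0, "dark")], (0.0, 24.0), schedule)
        assert arch.pct_sleep_dark == pytest.approx(100 * 0.5 / 10)
        assert arch.pct_sleep_light == pytest.approx(100 * 0.5 / 14)

    def test_conservation_sleep_plus_wake(self, rng, schedule):
        """Total sleep + total wake equals the window, in absolute hours."""
        counts = (rng.random(360 * 24) < 0.5).astype(float)
        bouts = detect_sleep_bouts(_trace(counts), EPOCH, 0.5)
        window = (0.0, 24.0)
        arch = sleep_metrics("m1", bouts, window, schedule)
        sleep_h = arch.pct_sleep_total / 100 * 24
        dark_h = arch.pct_sleep_dark / 100 * schedule.dark_hours
        light_h = arch.pct_sleep_light / 100 * schedule.light_hours
        assert np.isclose(sleep_h, dark_h + light_h)  # phase partition
        # sleep + wake == window: wake episodes are the exact complement
        bout_h = sum(b.duration for b in bouts) / 60.0
        assert np.isclose(sleep_h, bout_h)
        n_wake_expected = len(bouts) + 1 - (bouts[0].start == 0.0) - (
            bouts[-1].end >= 24.0
        )
        if n_wake_expected > 0:
            wake_h = arch.mean_wake_episode / 60.0 * n_wake_expected
            assert np.isclose(sleep_h + wake_h, 24.0)

    def test_matches_interval_oracle(self, rng, schedule):
        counts = (rng.random(360 * 30) < 0.4).astype(float)
        bouts = detect_sleep_bouts(_trace(counts), EPOCH, 1.0)
        window = (0.0, 30.0)
        arch = sleep_metrics("m1", bouts, window, schedule)
        ivs = [(b.start, b.end) for b in bouts]
        dark_ivs = schedule.phase_intervals(*window, "dark")
        total, dark, light = interval_sleep_oracle(ivs, window, dark_ivs)
        assert np.isclose(arch.pct_sleep_total, 100 * total / 30)
        assert np.isclose(arch.pct_sleep_dark, 100 * dark / sum(b - a for a, b in dark_ivs))


class TestSyntheticRecovery:
    def test_silent_wake_limit_recovers_planted_bouts_exactly(self):
        """With certain-nonzero wake counts, detection = planted bouts."""
        design = SyntheticDesign(
            seed=3,
            groups=(("CNT", 1),),
            sleep={"CNT": SleepParams(wake_rate=50.0)},  # P(zero wake epoch) ~ 0
        )
        trace, planted = gen_activity_trace(design, "CNT_01", duration=24.0)
        detected = detect_sleep_bouts(trace, EPOCH, 2.0)
        expected = [b for b in planted if b.duration >= 2.0]
        assert len(detected) == len(expected)
        for d, e in zip(detected, expected):
            assert np.isclose(d.start, e.start)
            assert np.isclose(d.duration, e.duration)

    def test_planted_phase_fractions_recovered(self):
        """Planted 70% light / 30% dark sleep recovered within MC error.

        A small threshold keeps the definitional exclusion of sub-threshold
        bouts negligible."""
        design = SyntheticDesign(seed=5, groups=(("CNT", 4),))
        pcts_l, pcts_d = [], []
        for aid, _ in design.animals():
            trace, _ = gen_activity_trace(design, aid, duration=96.0)
            bouts = detect_sleep_bouts(trace, EPOCH, 1.0 / 6.0)  # 10 s threshold
            arch = sleep_metrics(aid, bouts, (0.0, 96.0), design.schedule)
            pcts_l.append(arch.pct_sleep_light)
            pcts_d.append(arch.pct_sleep_dark)
        assert abs(np.mean(pcts_l) - 70.0) < 5.0
        assert abs(np.mean(pcts_d) - 30.0) < 5.0
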