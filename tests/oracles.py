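"""Independent brute-force oracles used to check the implementation.

Each oracle deliberately takes the slow, explicit route (enumeration, grid
search, normal equations, run-length scans) and shares no code with the
package's own computational path.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def groupby_bin_oracle(times, values, width, how):
    """Per-bin aggregate by explicit python loops over floor(t/width)."""
    n_bins = int(np.floor(max(times) / width)) + 1
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        vals = [v for t, v in zip(times, values) if k == int(np.floor(t / width))]
        if vals:
            out[k] = sum(vals) if how == "sum" else sum(vals) / len(vals)
    return out


def fold_oracle(starts, values, width, period):
    """Mean per (start mod period) slot by explicit accumulation."""
    n_per = int(round(period / width))
    slots = [[] for _ in range(n_per)]
    for s, v in zip(starts, values):
        if np.isfinite(v):
            slots[int(round((s % period) / width)) % n_per].append(v)
    return np.array([np.mean(s) if s else np.nan for s in slots])


def cosinor_grid_oracle(t, y, period=24.0, phi_step=0.01):
    """Best (M, A, phi) by scanning phi and solving the per-phi 2-parameter
    least squares min over (M, A) of ||y - M - A cos(2 pi (t-phi)/period)||."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = None
    for phi in np.arange(0, period, phi_step):
        c = np.cos(2 * np.pi * (t - phi) / period)
        X = np.column_stack([np.ones_like(t), c])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], phi)
    _, M, A, phi = best
    if A < 0:  # cos(x - phi - T/2) = -cos(x - phi)
        A, phi = -A, (phi + period / 2) % period
    return M, A, phi


def ancova_rss_oracle(y, group, covariate):
    """Nested-model F statistics via explicit normal equations."""
    y = np.asarray(y, float)
    covariate = np.asarray(covariate, float)
    levels = sorted(set(group))
    k, n = len(levels), len(y)
    D = np.column_stack([(np.asarray(group) == lev).astype(float) for lev in levels])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.column_stack([D, covariate])
    X_cov = np.column_stack([np.ones(n), covariate])
    rss_full, rss_cov, rss_grp = rss(X_full), rss(X_cov), rss(D)
    df_resid = n - k - 1
    F_group = ((rss_cov - rss_full) / (k - 1)) / (rss_full / df_resid)
    F_cov = (rss_grp - rss_full) / (rss_full / df_resid)
    return F_group, F_cov


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided p by full enumeration of all C(n1+n2, n1) label
    assignments of the pooled (tie-free) sample."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [u_of(idx) for idx in combinations(range(n1 + n2), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def rle_sleep_oracle(counts, epoch_s, min_minutes):
    """Sleep bouts as (start_epoch, n_epochs) by a scalar run-length scan."""
    min_epochs = int(np.ceil(min_minutes * 60.0 / epoch_s))
    bouts = []
    run_start = None
    for i, c in enumerate(list(counts) + [1.0]):  # sentinel terminates last run
        if c == 0 and run_start is None:
            run_start = i
        elif c != 0 and run_start is not None:
            if i - run_start >= min_epochs:
                bouts.append((run_start, i - run_start))
            run_start = None
    return bouts


def interval_sleep_oracle(bout_intervals, window, dark_intervals):
    """Sleep hours total/dark/light by explicit clipped intersections."""
    t0, t1 = window

    def inter(a0, a1, b0, b1):
        return max(0.0, min(a1, b1) - max(a0, b0))

    total = sum(inter(a, b, t0, t1) for a, b in bout_intervals)
    dark = sum(
        inter(a, b, max(d0, t0), min(d1, t1))
        for a, b in bout_intervals
        for d0, d1 in dark_intervals
    )
    return total, dark, total - dark


def polyline_auc_oracle(minutes, glucose):
    """Closed-form integral of the baseline-subtracted polyline."""
    base = glucose[0]
    auc = 0.0
    for (t0, g0), (t1, g1) in zip(
        zip(minutes[:-1], glucose[:-1]), zip(minutes[1:], glucose[1:])
    ):
        auc += ((g0 - base) + (g1 - base)) / 2.0 * (t1 - t0)
    return auc
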