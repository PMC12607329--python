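"""Group-level statistics.

Body mass is compared by one-way ANCOVA (group as a categorical factor,
littermate count as a continuous covariate) with Fisher's LSD post hoc on the
covariate-adjusted means; all other endpoints (time-series averages, cosinor
parameters, sleep metrics, GTT AUC, per-nucleus intensity ratios) are compared
pairwise by the Mann-Whitney U test.  No multiplicity adjustment is applied by
default (the LSD convention); Holm correction is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import scipy.stats as st
import statsmodels.api as sm

from .io_phenomaster import GTTCurve, MassRecord, ValidationError


@dataclass(frozen=True)
class AncovaResult:
    """One-way ANCOVA with a single continuous covariate.

    F statistics are Type-III style: each term's F compares the residual sum
    of squares of the full model against the model with that term dropped.
    ``adjusted_means`` are the fitted group means at the grand covariate mean.
    """

    groups: tuple[str, ...]
    n: int
    F_group: float
    df_group: tuple[int, int]
    p_group: float
    F_covariate: float
    df_covariate: tuple[int, int]
    p_covariate: float
    mse: float
    covariate_slope: float
    grand_covariate_mean: float
    adjusted_means: dict[str, float]
    # full-model parameter covariance scaled by mse, for LSD contrasts
    _xtx_inv: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PairwiseComparison:
    """One Fisher-LSD contrast between two covariate-adjusted group means."""

    group_a: str
    group_b: str
    difference: float
    se: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: Literal["exact", "normal_approx_tie_corrected"]
    n1: int
    n2: int


def ancova(
    masses: Sequence[MassRecord],
    response: Literal["mass_3w", "mass_10w"],
) -> AncovaResult:
    """ANCOVA of a mass endpoint on group with littermates as covariate."""
    y = np.array([getattr(m, response) for m in masses], dtype=float)
    x = np.array([m.littermates for m in masses], dtype=float)
    g = np.array([m.group for m in masses])
    return ancova_arrays(y, g, x)


def ancova_arrays(y: np.ndarray, group: np.ndarray, covariate: np.ndarray) -> AncovaResult:
    """ANCOVA on raw arrays (response, group labels, continuous covariate)."""
    y = np.asarray(y, float)
    covariate = np.asarray(covariate, float)
    group = np.asarray(group)
    levels = tuple(sorted(set(group.tolist())))
    k, n = len(levels), len(y)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    for lev in levels:
        if np.sum(group == lev) < 2:
            raise ValidationError(f"group {lev!r} has fewer than 2 records")
    if n - k - 1 <= 0:
        raise ValidationError("not enough residual degrees of freedom")

    D = np.column_stack([(group == lev).astype(float) for lev in levels])
    X_full = np.column_stack([D, covariate])
    if np.linalg.matrix_rank(X_full) < k + 1:
        raise ValidationError(
            "singular design: covariate 'littermates' is aliased with the "
            "group factor (constant within the design)"
        )

    fit_full = sm.OLS(y, X_full).fit()
    rss_full = float(fit_full.ssr)
    df_resid = n - k - 1
    mse = rss_full / df_resid

    # drop group -> intercept + covariate; drop covariate -> group dummies only
    rss_cov_only = float(sm.OLS(y, sm.add_constant(covariate)).fit().ssr)
    rss_group_only = float(sm.OLS(y, D).fit().ssr)

    F_group = ((rss_cov_only - rss_full) / (k - 1)) / mse
    F_cov = (rss_group_only - rss_full) / mse

    xbar = float(covariate.mean())
    beta = fit_full.params
    slope = float(beta[k])
    adjusted = {lev: float(beta[i] + slope * xbar) for i, lev in enumerate(levels)}

    return AncovaResult(
        groups=levels,
        n=n,
        F_group=float(F_group),
        df_group=(k - 1, df_resid),
        p_group=float(st.f.sf(F_group, k - 1, df_resid)),
        F_covariate=float(F_cov),
        df_covariate=(1, df_resid),
        p_covariate=float(st.f.sf(F_cov, 1, df_resid)),
        mse=float(mse),
        covariate_slope=slope,
        grand_covariate_mean=xbar,
        adjusted_means=adjusted,
        _xtx_inv=np.linalg.inv(X_full.T @ X_full),
    )


def lsd_posthoc(result: AncovaResult) -> list[PairwiseComparison]:
    """Fisher's LSD: unadjusted pairwise t tests on covariate-adjusted means,
    using the full-model residual mean square and its design geometry."""
    k = len(result.groups)
    df = result.df_group[1]
    out = []
    for ia, ib in combinations(range(k), 2):
        # contrast between adjusted means: slope column cancels
        c = np.zeros(k + 1)
        c[ia], c[ib] = 1.0, -1.0
        diff = result.adjusted_means[result.groups[ia]] - result.adjusted_means[
            result.groups[ib]
        ]
        se = float(np.sqrt(result.mse * c @ result._xtx_inv @ c))
        t = diff / se
        out.append(
            PairwiseComparison(
                result.groups[ia],
                result.groups[ib],
                float(diff),
                se,
                float(t),
                df,
                float(2 * st.t.sf(abs(t), df)),
            )
        )
    return out


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values (optional multiplicity control)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


EXACT_MAX_N = 8  # per-group cutoff for exact Mann-Whitney enumeration in auto mode


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``x`` (midranks for ties).  In ``auto``
    mode the p value is exact (full permutation distribution) when both
    samples have at most 8 observations and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        use_exact = len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties
    elif mode == "exact":
        if has_ties:
            raise ValidationError("exact mode requires tie-free data")
        use_exact = True
    else:
        use_exact = False

    res = st.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(
        U=float(res.statistic),
        p=float(res.pvalue),
        method="exact" if use_exact else "normal_approx_tie_corrected",
        n1=len(x),
        n2=len(y),
    )


def gtt_auc(curve: GTTCurve) -> float:
    """Net trapezoid-rule area of glucose above its minute-0 baseline,
    over the full sampling window (glucose units x minutes).  Excursions
    below baseline subtract (net AUC)."""
    if len(curve.minutes) < 2:
        raise ValidationError("GTT curve needs at least baseline and one sample")
    if curve.minutes[0] != 0:
        raise ValidationError("missing baseline (minute-0) sample")
    delta = curve.glucose - curve.baseline
    return float(np.trapezoid(delta, curve.minutes))
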