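"""Single-component cosinor regression at fixed period.

The model is

    y(t) = M + beta_c * cos(2*pi*t/tau) + beta_s * sin(2*pi*t/tau)

fitted by ordinary least squares, and re-expressed as

    y(t) = M + A * cos(2*pi*(t - phi)/tau)

with amplitude A = sqrt(beta_c^2 + beta_s^2) and acrophase
phi = (tau / 2*pi) * atan2(beta_s, beta_c) mod tau, in hours.  Under stable
light-dark entrainment the period is fixed (default 24 h), not estimated.

Acrophase is referenced to the recording's t = 0, which the acquisition
protocol places at dark onset (ZT0); an acrophase of 6 h therefore means the
fitted rhythm peaks 6 h after lights-off.

Feeding and locomotion are strongly skewed, so those channels are fitted on a
natural-log scale (``log_transform=True``); the amplitude is then in log units
and ``fold_change = exp(A)`` gives the peak/mesor ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_phenomaster import ValidationError
from .timeseries import BinnedSeries, overall_average


@dataclass(frozen=True)
class CosinorFit:
    """Mesor / amplitude / acrophase estimates for one series.

    ``degenerate`` marks a fit with no detectable rhythm (A numerically 0);
    its acrophase is reported as 0 by convention and must be excluded from
    downstream acrophase comparisons.  ``unreliable`` marks a fit on a record
    shorter than one full period.
    """

    channel: str
    period: float
    mesor: float
    amplitude: float
    acrophase: float
    beta_cos: float
    beta_sin: float
    residual_variance: float
    n_points: int
    log_transformed: bool
    log_offset: float
    degenerate: bool = False
    unreliable: bool = False

    @property
    def fold_change(self) -> float:
        """exp(A): peak-to-mesor ratio on the original scale (log variant)."""
        return float(np.exp(self.amplitude))

    def predict(self, t) -> np.ndarray:
        """Fitted curve M + A cos(2 pi (t - phi)/tau) at elapsed hours t."""
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase) / self.period
        )


def _auto_log_offset(values: np.ndarray) -> float:
    """Offset added before log: half the smallest positive value if zeros
    are present, else 0."""
    if np.any(values == 0):
        pos = values[values > 0]
        if len(pos) == 0:
            raise ValidationError("all values zero: log transform impossible")
        return float(pos.min() / 2.0)
    return 0.0


def fit_cosinor(
    binned: BinnedSeries,
    period: float = 24.0,
    log_transform: bool = False,
    log_offset: float | None = None,
) -> CosinorFit:
    """Least-squares cosinor fit to the non-missing bins of a series.

    Bin abscissae are the mean sample times per bin so the acrophase is
    unbiased regardless of the raw sampling density.  A span shorter than one
    period yields a warning and an ``unreliable`` flag; a rank-deficient
    design (all bins at one phase) is an error.
    """
    ok = binned.present
    t = binned.bin_times[ok]
    y = binned.values[ok].astype(float)
    if len(t) < 4:
        raise ValidationError("need at least 4 non-missing bins for a cosinor fit")

    unreliable = False
    if t[-1] - t[0] < period - binned.bin_width:
        warnings.warn(
            f"series spans {t[-1] - t[0]:.1f} h < one period ({period} h); "
            "fit flagged unreliable",
            stacklevel=2,
        )
        unreliable = True

    eps = 0.0
    if log_transform:
        eps = _auto_log_offset(y) if log_offset is None else float(log_offset)
        if np.any(y + eps <= 0):
            raise ValidationError("values + log_offset must be positive for log fit")
        y = np.log(y + eps)

    omega = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError(
            "rank-deficient cosinor design (all bins at one phase?)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = (float(b) for b in beta)
    resid = y - X @ beta
    dof = max(len(t) - 3, 1)
    amp = float(np.hypot(bc, bs))

    scale = max(abs(mesor), np.max(np.abs(y)), 1.0)
    degenerate = amp <= 1e-10 * scale
    phi = 0.0 if degenerate else float((period / (2 * np.pi)) * np.arctan2(bs, bc) % period)

    return CosinorFit(
        channel=binned.channel,
        period=period,
        mesor=mesor,
        amplitude=amp,
        acrophase=phi,
        beta_cos=bc,
        beta_sin=bs,
        residual_variance=float(resid @ resid / dof),
        n_points=len(t),
        log_transformed=log_transform,
        log_offset=eps,
        degenerate=degenerate,
        unreliable=unreliable,
    )


def mesor_equivalence_check(
    fit: CosinorFit, binned: BinnedSeries, tol: float = 1e-8
) -> bool:
    """Self-diagnostic: does the mesor equal the plain series average?

    Exact (to rounding) for gap-free sampling over an integer number of
    periods, where the cosine/sine regressors are orthogonal to the
    intercept; legitimately false when gaps break that orthogonality.
    Only meaningful for linear (non-log) fits.
    """
    if fit.log_transformed:
        ok = binned.present
        mean = float(np.mean(np.log(binned.values[ok] + fit.log_offset)))
    else:
        mean = overall_average(binned)
    scale = max(abs(mean), abs(fit.mesor), 1.0)
    return bool(abs(fit.mesor - mean) <= tol * scale)
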