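"""First-order decay fits for transcription shut-off time courses.

A GAL-driven gene is repressed with glucose at t=0 and the target mRNA is
followed by qPCR, normalized against a stable reference transcript
(``ACT1``-style) at every timepoint. Under first-order turnover the
relative abundance is ``r(t) = exp(-k t)`` up to a scale, so ``ln r`` is
fit by ordinary least squares with a *free* intercept (robust to
mis-scaling of the t=0 sample); the half-life is ``ln 2 / k`` and its 95%
CI comes from the t-distribution of the slope standard error, with a
residual-resampling bootstrap as an alternative. Replicate courses are
pooled into one regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import DecayCourse

LN2 = math.log(2.0)


@dataclass
class DecayFit:
    """A first-order decay fit. ``half_life = ln2 / rate_k``; a
    non-decaying fit (k <= 0) carries ``half_life = inf`` and is flagged."""

    rate_k: float
    half_life: float
    ci95: tuple[float, float]  # minutes
    n_points: int
    residual_sd: float
    intercept: float
    decaying: bool = True
    # retained observations, so folds between fits can bootstrap residuals
    times: np.ndarray = field(default=None, repr=False)
    log_values: np.ndarray = field(default=None, repr=False)


def normalize_shutoff(course: DecayCourse) -> np.ndarray:
    """Relative abundance ``r(t) = (target/reference)(t) / (target/reference)(0)``.

    ``r(0)`` is exactly 1. A zero (or negative) reference value is an error.
    """
    ref = np.asarray(course.reference_quantity, dtype=float)
    if np.any(ref <= 0):
        raise ValueError(f"{course.gene}/{course.replicate_id}: nonpositive reference quantity")
    ratio = np.asarray(course.target_quantity, dtype=float) / ref
    return ratio / ratio[0]


def fit_first_order(
    times: Sequence[float],
    rel_abundance: Sequence[float],
    conf: float = 0.95,
) -> DecayFit:
    """Least-squares fit of ``ln r = -k t + b`` on (pooled) points.

    Requires >= 2 distinct timepoints and positive abundances. The
    half-life CI maps the slope's t-based CI through ``ln2 / k``; when the
    interval touches non-decaying slopes the upper bound is infinite.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(rel_abundance, dtype=float)
    if t.shape != r.shape:
        raise ValueError("times and abundances must have the same shape")
    if np.unique(t).size < 2:
        raise ValueError("a decay fit needs at least two distinct timepoints")
    if np.any(r <= 0):
        raise ValueError("relative abundances must be positive")
    y = np.log(r)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    dof = t.size - 2
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    sxx = float(((t - t.mean()) ** 2).sum())
    se_slope = residual_sd / math.sqrt(sxx) if sxx > 0 else np.inf
    tcrit = stats.t.ppf(0.5 + conf / 2.0, dof) if dof > 0 else np.inf
    k = -float(slope)
    # slope CI -> k CI -> half-life CI (monotone decreasing map t1/2 = ln2/k)
    k_lo, k_hi = k - tcrit * se_slope, k + tcrit * se_slope
    if k <= 0:
        return DecayFit(
            rate_k=k, half_life=math.inf, ci95=(LN2 / k_hi if k_hi > 0 else math.inf, math.inf),
            n_points=t.size, residual_sd=residual_sd, intercept=float(intercept),
            decaying=False, times=t, log_values=y,
        )
    hl_lo = LN2 / k_hi if k_hi > 0 else math.inf
    hl_hi = LN2 / k_lo if k_lo > 0 else math.inf
    return DecayFit(
        rate_k=k, half_life=LN2 / k, ci95=(hl_lo, hl_hi), n_points=t.size,
        residual_sd=residual_sd, intercept=float(intercept), decaying=True,
        times=t, log_values=y,
    )


def fit_courses(courses: Iterable[DecayCourse], conf: float = 0.95) -> DecayFit:
    """Normalize each replicate course and fit all points in one pooled regression."""
    courses = list(courses)
    if not courses:
        raise ValueError("no courses to fit")
    t = np.concatenate([np.asarray(c.timepoints, dtype=float) for c in courses])
    r = np.concatenate([normalize_shutoff(c) for c in courses])
    return fit_first_order(t, r, conf=conf)


def bootstrap_half_life_ci(
    fit: DecayFit, n_boot: int = 1000, seed: int = 0, conf: float = 0.95
) -> tuple[float, float]:
    """Residual-resampling bootstrap CI for the half-life (alternative to
    the analytic t-interval)."""
    if fit.times is None:
        raise ValueError("fit does not retain its observations")
    rng = np.random.default_rng(seed)
    t, y = fit.times, fit.log_values
    yhat = -fit.rate_k * t + fit.intercept
    resid = y - yhat
    halves = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        slope, _ = np.polyfit(t, yb, 1)
        halves.append(LN2 / -slope if slope < 0 else math.inf)
    lo, hi = np.percentile(halves, [50 * (1 - conf), 50 * (1 + conf)])
    return float(lo), float(hi)


def stabilization_fold(
    fit_a: DecayFit,
    fit_b: DecayFit,
    n_boot: int | None = None,
    seed: int = 0,
    conf: float = 0.95,
) -> tuple[float, tuple[float, float] | None]:
    """Half-life ratio ``fit_a / fit_b`` (fold stabilization of condition a).

    With ``n_boot`` set, a residual-resampling bootstrap CI for the fold
    is returned as well. An infinite half-life propagates to an infinite
    fold (flagged upstream by ``decaying=False``).
    """
    fold = fit_a.half_life / fit_b.half_life
    if n_boot is None:
        return fold, None
    if fit_a.times is None or fit_b.times is None:
        raise ValueError("fits do not retain their observations")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_boot):
        hl = []
        for f in (fit_a, fit_b):
            yhat = -f.rate_k * f.times + f.intercept
            resid = f.log_values - yhat
            yb = yhat + rng.choice(resid, size=resid.size, replace=True)
            slope, _ = np.polyfit(f.times, yb, 1)
            hl.append(LN2 / -slope if slope < 0 else math.inf)
        folds.append(hl[0] / hl[1])
    lo, hi = np.percentile(folds, [50 * (1 - conf), 50 * (1 + conf)])
    return fold, (float(lo), float(hi))
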