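"""Cross-ROI lag estimation and the arousal activity sequence.

The relative timing of arousal-locked activity across regions is quantified
by cross-correlating each ROI's locked mean against a global reference (the
mean across all ROIs, standing in for the whole-thalamus or whole-cortex
signal).  At every integer-step shift within +/- max_lag the Pearson
correlation over the *overlapping* samples is computed (no zero padding,
which would bias lags toward zero on 30 s windows); the lag is the shift
maximizing r.  Negative lag means the ROI leads the reference.

Uncertainty comes from resampling arousals with replacement — the same
resample indices are applied to every ROI so the reference is rebuilt
consistently — or hierarchically (subjects with replacement, then arousals
within each drawn subject, accumulating until a target event total) to
propagate between-subject variability.  A breathhold control applies the
identical machinery to breathhold-release-locked windows, and the purely
vascular lags it yields are subtracted from the arousal lags per ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DegenerateCorrelationError,
    InvalidConfigError,
    NoPositivePeakError,
    UnstableEstimateError,
)
from .locked import LockedEnsemble

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LagEstimate:
    """Cross-correlation lag of one ROI against the global reference."""

    roi: str
    lag: float  # seconds; negative = ROI leads the reference
    r: float
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")


@dataclass(frozen=True)
class SequenceResult:
    """ROIs ordered by lag, with the spanned range."""

    order: tuple[str, ...]
    lag_range: float
    estimates: tuple[LagEstimate, ...]


def _pearson_per_shift(x: np.ndarray, y: np.ndarray, max_shift: int):
    """Pearson r of x[t] vs y[t-k] over the overlap, for k in [-K, K].

    Vectorized over shifts via the raw cross-correlation and cumulative sums
    of the overlapping segments.  Returns (shifts, r) with r NaN where either
    segment has zero variance.
    """
    n = x.size
    if y.size != n:
        raise InvalidConfigError("series must share one time axis")
    K = min(max_shift, n - 2)
    shifts = np.arange(-K, K + 1)
    # np.correlate(x, y, 'full')[n-1+k] = sum_t x[t] y[t-k]
    sxy = np.correlate(x, y, "full")[n - 1 + shifts]

    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    # overlap for shift k: x[max(k,0) : n+min(k,0)], y shifted by -k
    xa = np.maximum(shifts, 0)
    xb = n + np.minimum(shifts, 0)
    m = (xb - xa).astype(float)
    sx = cx[xb] - cx[xa]
    sxx = cxx[xb] - cxx[xa]
    ya = np.maximum(-shifts, 0)
    yb = n + np.minimum(-shifts, 0)
    sy = cy[yb] - cy[ya]
    syy = cyy[yb] - cyy[ya]

    vx = sxx - sx * sx / m
    vy = syy - sy * sy / m
    cov = sxy - sx * sy / m
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    r[(vx <= 1e-30) | (vy <= 1e-30)] = np.nan
    return shifts, np.clip(r, -1.0, 1.0)


def _pick_peak(shifts: np.ndarray, r: np.ndarray, positive_only: bool) -> tuple[int, float]:
    valid = ~np.isnan(r)
    if not valid.any():
        raise DegenerateCorrelationError("zero-variance overlap at every shift")
    if positive_only:
        valid &= r > 0
        if not valid.any():
            raise NoPositivePeakError("no positive correlation at any shift")
    rmax = np.nanmax(np.where(valid, r, -np.inf))
    at_max = valid & (r >= rmax - 1e-12)
    # ties: smallest |lag|, then negative before positive
    cand = shifts[at_max]
    order = np.lexsort((cand > 0, np.abs(cand)))
    best = int(cand[order[0]])
    return best, float(r[shifts == best][0])


def xcorr_lag(roi_mean: np.ndarray, reference_mean: np.ndarray, step: float,
              max_lag: float = 10.0, positive_only: bool = False,
              roi: str = "", refine: bool = True) -> LagEstimate:
    """Lag (s) maximizing the per-shift Pearson correlation with the reference.

    ``step`` is the sampling interval of both means (the upsampled grid).
    Positive lag: the ROI's waveform trails the reference.

    With ``refine`` (the default) the discrete peak is sharpened by
    three-point parabolic interpolation of r around the maximizing shift,
    giving a sub-sample lag.  True lags generically fall between grid cells;
    without refinement the estimator is a step function of the data, which
    both quantizes the estimate and degrades bootstrap interval calibration.
    Tie-breaking (smallest |lag|, then negative) applies to the discrete peak
    before refinement; ``refine=False`` returns the raw grid argmax.
    """
    if max_lag <= 0:
        raise InvalidConfigError("max_lag must be positive")
    K = int(round(max_lag / step))
    shifts, r = _pearson_per_shift(np.asarray(roi_mean, float),
                                   np.asarray(reference_mean, float), K)
    k, rbest = _pick_peak(shifts, r, positive_only)
    lag = float(k) * step
    if refine:
        i = int(np.flatnonzero(shifts == k)[0])
        if 0 < i < shifts.size - 1:
            rm, r0, rp = r[i - 1], r[i], r[i + 1]
            if np.isfinite(rm) and np.isfinite(rp):
                denom = rm - 2 * r0 + rp
                if denom < -1e-15:
                    dk = float(np.clip(0.5 * (rm - rp) / denom, -0.5, 0.5))
                    lag = (k + dk) * step
    return LagEstimate(roi=roi, lag=lag, r=rbest)


def mean_reference(means: dict[str, np.ndarray]) -> np.ndarray:
    """Default global reference: unweighted mean across all ROI means."""
    return np.mean(list(means.values()), axis=0)


def _lags_for_means(means: dict[str, np.ndarray], step, max_lag, positive_only,
                    reference=mean_reference) -> dict[str, tuple[float, float]]:
    ref = reference(means)
    out = {}
    for name, m in means.items():
        est = xcorr_lag(m, ref, step, max_lag, positive_only, roi=name)
        out[name] = (est.lag, est.r)
    return out


def _check_aligned(ensembles: dict[str, LockedEnsemble]):
    first = next(iter(ensembles.values()))
    for ens in ensembles.values():
        if ens.n_events != first.n_events or ens.times.size != first.times.size:
            raise InvalidConfigError("ensembles must share one event set and time axis")
    return first


def bootstrap_lags(ensembles: dict[str, LockedEnsemble], n: int = 1000,
                   seed: int | None = 0, max_lag: float = 10.0,
                   positive_only: bool = False,
                   reference=mean_reference) -> dict[str, LagEstimate]:
    """Per-ROI lags with percentile bootstrap CIs over arousals.

    Every resample draws one index set and applies it to all ROIs, so the
    reference is rebuilt from the same resampled events.  A resample in which
    the correlation is degenerate contributes NaN; if more than half fail the
    estimate is reported unstable.
    """
    first = _check_aligned(ensembles)
    step = first.step
    n_ev = first.n_events
    names = list(ensembles)
    point = _lags_for_means({k: v.matrix.mean(axis=0) for k, v in ensembles.items()},
                            step, max_lag, positive_only, reference)
    rng = np.random.default_rng(seed)
    boots = {k: np.empty(n) for k in names}
    failures = 0
    for b in range(n):
        idx = rng.integers(0, n_ev, n_ev)
        means = {k: ensembles[k].matrix[idx].mean(axis=0) for k in names}
        try:
            res = _lags_for_means(means, step, max_lag, positive_only, reference)
        except (DegenerateCorrelationError, NoPositivePeakError):
            failures += 1
            for k in names:
                boots[k][b] = np.nan
            continue
        for k in names:
            boots[k][b] = res[k][0]
    if failures > n / 2:
        raise UnstableEstimateError(f"{failures}/{n} bootstrap resamples degenerate")
    out = {}
    for k in names:
        vals = boots[k][~np.isnan(boots[k])]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[k] = LagEstimate(roi=k, lag=point[k][0], r=point[k][1],
                             ci_lo=float(lo), ci_hi=float(hi))
    return out


def hierarchical_bootstrap_lags(ensembles: dict[str, LockedEnsemble],
                                target_total: int | None = None, n: int = 1000,
                                seed: int | None = 0, max_lag: float = 10.0,
                                positive_only: bool = False,
                                reference=mean_reference) -> dict[str, LagEstimate]:
    """Two-level bootstrap: subjects with replacement, then their arousals.

    Subjects are drawn with replacement; for each drawn subject its arousals
    are resampled with replacement (same count the subject contributed), and
    drawing continues until the accumulated event total reaches
    ``target_total`` (default: the observed total).  Requires per-row subject
    ids on the ensembles; with a single subject this degrades to the flat
    bootstrap (with a warning), since there is no between-subject level.
    """
    first = _check_aligned(ensembles)
    if first.subjects is None:
        raise InvalidConfigError("hierarchical bootstrap requires per-event subject ids")
    subjects = np.asarray(first.subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        logger.warning("single subject: falling back to flat bootstrap")
        return bootstrap_lags(ensembles, n, seed, max_lag, positive_only, reference)
    if target_total is None:
        target_total = first.n_events
    step = first.step
    names = list(ensembles)
    subj_rows = {s: np.flatnonzero(subjects == s) for s in uniq}
    point = _lags_for_means({k: v.matrix.mean(axis=0) for k, v in ensembles.items()},
                            step, max_lag, positive_only, reference)
    rng = np.random.default_rng(seed)
    boots = {k: np.empty(n) for k in names}
    failures = 0
    for b in range(n):
        idx_parts = []
        total = 0
        while total < target_total:
            s = uniq[rng.integers(0, uniq.size)]
            rows = subj_rows[s]
            idx_parts.append(rows[rng.integers(0, rows.size, rows.size)])
            total += rows.size
        idx = np.concatenate(idx_parts)
        means = {k: ensembles[k].matrix[idx].mean(axis=0) for k in names}
        try:
            res = _lags_for_means(means, step, max_lag, positive_only, reference)
        except (DegenerateCorrelationError, NoPositivePeakError):
            failures += 1
            for k in names:
                boots[k][b] = np.nan
            continue
        for k in names:
            boots[k][b] = res[k][0]
    if failures > n / 2:
        raise UnstableEstimateError(f"{failures}/{n} hierarchical resamples degenerate")
    out = {}
    for k in names:
        vals = boots[k][~np.isnan(boots[k])]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[k] = LagEstimate(roi=k, lag=point[k][0], r=point[k][1],
                             ci_lo=float(lo), ci_hi=float(hi))
    return out


def sequence(estimates: dict[str, LagEstimate] | list[LagEstimate]) -> SequenceResult:
    """Order ROIs by lag (ascending: leaders first) and report the range."""
    if isinstance(estimates, dict):
        ests = list(estimates.values())
    else:
        ests = list(estimates)
    if len(ests) < 2:
        raise InvalidConfigError("sequence needs at least two ROIs")
    ests.sort(key=lambda e: e.lag)
    lags_s = [e.lag for e in ests]
    return SequenceResult(order=tuple(e.roi for e in ests),
                          lag_range=float(lags_s[-1] - lags_s[0]),
                          estimates=tuple(ests))


def breathhold_lags(ensembles: dict[str, LockedEnsemble], n: int = 1000,
                    seed: int | None = 0, max_lag: float = 10.0,
                    hierarchical: bool = False,
                    target_total: int | None = None) -> dict[str, LagEstimate]:
    """Vascular lags from breathhold-release-locked ensembles.

    The same ensemble + cross-correlation machinery as for arousals, applied
    to windows locked to breathhold release; ensembles are expected already
    windowed (-20...+20 s) and motion-excluded upstream.
    """
    if hierarchical:
        return hierarchical_bootstrap_lags(ensembles, target_total, n, seed, max_lag)
    return bootstrap_lags(ensembles, n, seed, max_lag)


def hemodynamic_correct(arousal: dict[str, LagEstimate],
                        breathhold: dict[str, LagEstimate]) -> dict[str, LagEstimate]:
    """Subtract each ROI's breathhold (vascular) lag from its arousal lag."""
    missing = set(arousal) - set(breathhold)
    if missing:
        raise KeyError(f"no breathhold lag for ROIs: {sorted(missing)}")
    out = {}
    for k, est in arousal.items():
        out[k] = replace(est, lag=est.lag - breathhold[k].lag,
                         ci_lo=float("nan"), ci_hi=float("nan"))
    return out
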