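"""Arousal-locked ensembles: windowing, latency, binned tests, PCA modes.

Each ROI trace is linearly upsampled (default 4x, e.g. 247 ms TR -> 61.75 ms)
so event alignment is precise, then a window from 10 s before to 20 s after
each arousal is cut out, aligned at the sample nearest the event.  Rows are
baseline-centered to the mean of the first 3 s of the window (-10 to -7 s).
The ensemble mean and its standard error (std / sqrt(n events)) summarize the
response; response timing is the 20% latency — the earliest post-baseline
time at which the mean deviates from baseline by 20% of its extremal
deviation — with a bootstrap-over-events percentile confidence interval.
Per-ROI significance across time uses 1 s bins with Bonferroni correction;
population structure across ROIs comes from an SVD of the centered means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core import (
    DegenerateSignalError,
    EmptyEnsembleError,
    InvalidConfigError,
    ROITimeseries,
    SampledSeries,
)

BASELINE_WINDOW = (-10.0, -7.0)


@dataclass(frozen=True)
class LockedEnsemble:
    """Event-aligned window matrix (events x timepoints) for one ROI."""

    matrix: np.ndarray
    times: np.ndarray  # seconds relative to arousal
    centered: bool = False
    subjects: tuple | None = None  # per-row subject ids, for hierarchical resampling

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.atleast_2d(np.asarray(self.matrix, float)))
        object.__setattr__(self, "times", np.asarray(self.times, float))
        if self.matrix.shape[1] != self.times.size:
            raise InvalidConfigError("ensemble matrix and time axis disagree")
        if self.subjects is not None and len(self.subjects) != self.matrix.shape[0]:
            raise InvalidConfigError("one subject id per ensemble row required")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class LatencyEstimate:
    """A 20%-threshold latency with its bootstrap confidence interval."""

    latency: float
    ci_lo: float
    ci_hi: float
    threshold: float = 0.2
    polarity: str = "absolute"
    n_boot: int = 1000


@dataclass(frozen=True)
class PCAModes:
    """SVD decomposition of the ROI x time matrix of centered means."""

    components: np.ndarray  # components x time
    loadings: np.ndarray  # ROIs x components
    variance_fractions: np.ndarray


def upsample(ts: ROITimeseries, factor: int = 4) -> ROITimeseries:
    """Linearly interpolate a trace to ``factor`` times its sampling rate.

    Samples on the original grid are preserved exactly; the new interval is
    TR / factor.  The TR attribute keeps the acquisition TR.
    """
    if int(factor) != factor or factor < 1:
        raise InvalidConfigError(f"upsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return ts
    s = ts.series
    n_new = (s.n - 1) * factor + 1
    new_dt = s.dt / factor
    # exact on-grid preservation: fill originals, interpolate between
    out = np.empty(n_new)
    out[::factor] = s.values
    for k in range(1, factor):
        w = k / factor
        out[k::factor] = (1 - w) * s.values[:-1] + w * s.values[1:]
    return ROITimeseries(name=ts.name,
                         series=SampledSeries(out, start=s.start, dt=new_dt), tr=ts.tr)


def extract_windows(ts: ROITimeseries, event_times, pre: float = 10.0, post: float = 20.0,
                    subjects=None) -> LockedEnsemble:
    """Cut event-aligned windows from an (upsampled) trace.

    Each row is aligned at the sample nearest the event time.  Events whose
    window would cross the run edges are dropped.  ``subjects`` optionally
    attaches a subject id per event (kept only for retained events).
    """
    s = ts.series
    step = s.dt
    n_pre = int(round(pre / step))
    n_post = int(round(post / step))
    rel_times = (np.arange(n_pre + n_post + 1) - n_pre) * step
    rows, kept_subjects = [], []
    event_times = np.asarray(event_times, dtype=float)
    for i, et in enumerate(event_times):
        center = int(round((et - s.start) / step))
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi >= s.n:
            continue
        rows.append(s.values[lo:hi + 1])
        if subjects is not None:
            kept_subjects.append(subjects[i])
    if not rows:
        raise EmptyEnsembleError("no event window fits inside the run")
    return LockedEnsemble(
        matrix=np.vstack(rows), times=rel_times,
        subjects=tuple(kept_subjects) if subjects is not None else None,
    )


def _baseline_mask(times: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise InvalidConfigError(f"baseline window {window} outside ensemble time axis")
    return mask


def baseline_center(ens: LockedEnsemble, window=BASELINE_WINDOW) -> LockedEnsemble:
    """Subtract each row's mean over the baseline window (idempotent)."""
    mask = _baseline_mask(ens.times, window)
    centered = ens.matrix - ens.matrix[:, mask].mean(axis=1, keepdims=True)
    return replace(ens, matrix=centered, centered=True)


def ensemble_mean_sem(ens: LockedEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard error (std with n-1 / sqrt(n)) across events."""
    m = ens.matrix.mean(axis=0)
    n = ens.n_events
    if n > 1:
        sem = ens.matrix.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(m)
    return m, sem


def latency20(values: np.ndarray, times: np.ndarray, polarity: str = "absolute",
              baseline_window=BASELINE_WINDOW, threshold: float = 0.2) -> float:
    """Earliest post-baseline time at which the signal reaches 20% of its extremum.

    The baseline is the mean over ``baseline_window``; the extremum is the
    largest absolute (or, with ``polarity='positive'``, largest positive)
    deviation from baseline after the baseline window.  The latency is the
    first time after the baseline window at which the deviation on the side
    of the extremum reaches ``threshold`` times the extremal deviation.
    """
    if polarity not in ("absolute", "positive"):
        raise InvalidConfigError(f"unknown polarity {polarity!r}")
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    base_mask = _baseline_mask(times, baseline_window)
    dev = values - values[base_mask].mean()
    search = times > baseline_window[1]
    d = dev[search]
    if polarity == "positive":
        ext = float(np.max(d))
        if ext <= 0:
            raise DegenerateSignalError("no positive deviation from baseline")
        signed = d
    else:
        i_ext = int(np.argmax(np.abs(d)))
        ext = float(np.abs(d[i_ext]))
        if ext == 0:
            raise DegenerateSignalError("signal equals baseline everywhere")
        signed = d * np.sign(d[i_ext])
    hit = signed >= threshold * ext
    idx = int(np.argmax(hit))
    return float(times[search][idx])


def bootstrap_latency(ens: LockedEnsemble, polarity: str = "absolute", n: int = 1000,
                      seed: int | None = 0, baseline_window=BASELINE_WINDOW,
                      threshold: float = 0.2) -> LatencyEstimate:
    """Latency of the ensemble mean with a percentile bootstrap CI over events.

    Events (rows) are resampled with replacement ``n`` times; the latency of
    each resampled mean forms the bootstrap distribution, and the CI is its
    2.5/97.5 percentiles.  Deterministic for a fixed seed.
    """
    if ens.n_events < 2:
        raise EmptyEnsembleError("bootstrap needs at least two events")
    point = latency20(ens.matrix.mean(axis=0), ens.times, polarity, baseline_window, threshold)
    rng = np.random.default_rng(seed)
    lats = np.empty(n)
    failed = 0
    for b in range(n):
        idx = rng.integers(0, ens.n_events, ens.n_events)
        try:
            lats[b] = latency20(ens.matrix[idx].mean(axis=0), ens.times,
                                polarity, baseline_window, threshold)
        except DegenerateSignalError:
            lats[b] = np.nan
            failed += 1
    ok = lats[~np.isnan(lats)]
    if ok.size == 0:
        raise DegenerateSignalError("every bootstrap resample was degenerate")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return LatencyEstimate(latency=point, ci_lo=float(lo), ci_hi=float(hi),
                           threshold=threshold, polarity=polarity, n_boot=n)


def binned_test(ens: LockedEnsemble, other: LockedEnsemble | None = None,
                bin_width: float = 1.0, n_rois_tested: int = 1,
                alpha: float = 0.05) -> dict:
    """Per-1-s-bin two-sided t-tests with Bonferroni correction.

    One-sample mode tests each bin mean against zero (the ensemble should be
    baseline-centered first); paired mode tests the per-event difference
    between two ensembles with equal row counts.  The correction family is
    (number of bins) x ``n_rois_tested``.
    """
    times = ens.times
    t0, t1 = times[0], times[-1]
    edges = np.arange(t0, t1 + bin_width / 2, bin_width)
    if not np.isclose(edges[-1], t1 + 0.0, atol=ens.step):
        raise InvalidConfigError("bins must tile the window exactly")
    data = ens.matrix
    if other is not None:
        if other.n_events != ens.n_events:
            raise InvalidConfigError("paired test requires equal event counts")
        data = ens.matrix - other.matrix
    n_bins = edges.size - 1
    pvals = np.ones(n_bins)
    tstats = np.zeros(n_bins)
    centers = np.empty(n_bins)
    for i in range(n_bins):
        mask = (times >= edges[i]) & (times < edges[i + 1])
        if i == n_bins - 1:
            mask |= np.isclose(times, edges[-1])
        centers[i] = 0.5 * (edges[i] + edges[i + 1])
        bin_means = data[:, mask].mean(axis=1)
        if np.allclose(bin_means, bin_means[0]):
            # zero variance: identical values; significant iff nonzero mean
            tstats[i], pvals[i] = (np.inf, 0.0) if bin_means[0] != 0 else (0.0, 1.0)
            continue
        tstats[i], pvals[i] = stats.ttest_1samp(bin_means, 0.0)
    family = n_bins * n_rois_tested
    corrected = np.minimum(pvals * family, 1.0)
    return {
        "bin_centers": centers,
        "t": tstats,
        "p": pvals,
        "p_corrected": corrected,
        "significant": corrected < alpha,
    }


def pca_modes(means: np.ndarray, times: np.ndarray,
              baseline_window=BASELINE_WINDOW) -> PCAModes:
    """SVD activity modes of the ROI x time matrix of locked means.

    Each row (one ROI's mean response) is centered to its baseline-window
    mean, then decomposed: components are temporal modes, loadings give each
    ROI's weight on each mode, and variance fractions are the normalized
    squared singular values.
    """
    means = np.atleast_2d(np.asarray(means, float))
    if means.shape[0] < 2:
        raise InvalidConfigError("PCA needs at least two ROIs")
    mask = _baseline_mask(np.asarray(times, float), baseline_window)
    centered = means - means[:, mask].mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise DegenerateSignalError("centered mean matrix has rank 0")
    return PCAModes(components=vt, loadings=u * s, variance_fractions=s**2 / total)
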