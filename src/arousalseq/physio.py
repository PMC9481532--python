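"""Cardiac/respiratory phase estimation and dynamic physiological regression.

Fast fMRI resolves cardiac and respiratory oscillations directly, so they
appear in ROI traces as quasi-periodic contamination whose fundamental
frequency drifts over a session.  Cleaning follows the RETROICOR idea —
regress sines and cosines of the cardiac and respiratory phases (first and
second harmonics) out of the BOLD signal — but with betas re-estimated in
long sliding windows (1000 s window, 400 s step) and linearly interpolated
across time, so the fitted amplitude and phase can track slow drifts.

Cardiac phase comes from peak detection on the band-passed pulse waveform
(0.2-10 Hz): phase ramps linearly 0 -> 2*pi between consecutive peaks.
Respiratory phase is the angle of the analytic signal after an FIR band-pass
(0.16-0.4 Hz).  Band-limited amplitude envelopes (|Hilbert|) quantify how
respiration and pulse strength change around arousal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    DegenerateSignalError,
    InsufficientSignalError,
    InvalidConfigError,
    ROITimeseries,
    SampledSeries,
)

logger = logging.getLogger(__name__)

CARDIAC_BAND = (0.7, 1.8)
RESPIRATORY_BAND = (0.16, 0.4)
#: minimum plausible inter-beat interval (s); 0.4 s ~ 150 bpm
MIN_PEAK_DISTANCE_S = 0.4


@dataclass(frozen=True)
class PhysioRecording:
    """Simultaneously sampled pulse and respiration waveforms."""

    cardiac: np.ndarray
    respiratory: np.ndarray
    fs: float
    start: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.cardiac, float)
        r = np.asarray(self.respiratory, float)
        object.__setattr__(self, "cardiac", c)
        object.__setattr__(self, "respiratory", r)
        if c.size != r.size:
            raise InvalidConfigError("cardiac and respiratory channels differ in length")
        if self.fs < 20.0:
            raise InvalidConfigError("physiological sampling rate must be >= 20 Hz")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.cardiac.size) / self.fs

    @property
    def duration(self) -> float:
        return self.cardiac.size / self.fs


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous physiological phase wrapped to [0, 2*pi), on a time grid."""

    phase: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phase", np.asarray(self.phase, float))
        object.__setattr__(self, "times", np.asarray(self.times, float))


@dataclass(frozen=True)
class SlidingGLMConfig:
    """Sliding-window regression settings for dynamic cleaning."""

    window: float = 1000.0
    step: float = 400.0
    harmonics: tuple[int, ...] = (1, 2)
    include_drift: bool = True

    def __post_init__(self):
        if self.step > self.window:
            raise InvalidConfigError("step must not exceed window length")
        if not self.harmonics:
            raise InvalidConfigError("at least one harmonic required")


def _fir_bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
                  numtaps: int | None = None) -> np.ndarray:
    lo, hi = band
    if hi >= fs / 2:
        raise InvalidConfigError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    if numtaps is None:
        # ~3 cycles of the low edge; enough roll-off for <=1% passband ripple
        numtaps = int(min(3 * fs / lo, x.size // 3 * 2 - 1))
        numtaps |= 1  # odd for a type-I linear-phase filter
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x, padtype="even")


def cardiac_phase(rec: PhysioRecording, grid_times: np.ndarray) -> PhaseSeries:
    """Cardiac phase from pulse peaks, resampled onto ``grid_times``.

    The waveform is band-passed 0.2-10 Hz, peaks are detected with a 0.4 s
    minimum separation, and phase ramps linearly from 0 to 2*pi between
    consecutive peaks (0 at each peak).
    """
    if rec.duration < 10.0:
        raise InsufficientSignalError("need >= 10 s of pulse signal")
    filtered = _fir_bandpass(rec.cardiac, rec.fs, (0.2, min(10.0, rec.fs / 2 * 0.95)))
    min_dist = max(int(MIN_PEAK_DISTANCE_S * rec.fs), 1)
    peaks, _ = signal.find_peaks(filtered, distance=min_dist,
                                 prominence=0.25 * np.std(filtered))
    if peaks.size < 3:
        raise InsufficientSignalError(f"only {peaks.size} cardiac peaks detected")
    peak_t = rec.times[peaks]
    # unwrapped phase is 2*pi*k at the k-th peak, linear in between
    unwrapped = np.interp(grid_times, peak_t, 2 * np.pi * np.arange(peaks.size))
    return PhaseSeries(phase=np.mod(unwrapped, 2 * np.pi), times=np.asarray(grid_times, float))


def respiratory_phase(rec: PhysioRecording, grid_times: np.ndarray,
                      band: tuple[float, float] = RESPIRATORY_BAND) -> PhaseSeries:
    """Respiratory phase: FIR band-pass then analytic-signal angle."""
    if rec.duration < 60.0:
        raise InsufficientSignalError("need >= 60 s of respiration for filter transients")
    x = rec.respiratory
    if np.ptp(x) == 0:
        raise DegenerateSignalError("respiratory channel is constant")
    filtered = _fir_bandpass(x, rec.fs, band)
    phase = np.angle(signal.hilbert(filtered))
    unwrapped = np.unwrap(phase)
    on_grid = np.interp(grid_times, rec.times, unwrapped)
    return PhaseSeries(phase=np.mod(on_grid, 2 * np.pi), times=np.asarray(grid_times, float))


def _phase_regressors(cardiac: PhaseSeries, resp: PhaseSeries, harmonics) -> np.ndarray:
    cols = []
    for ph in (cardiac.phase, resp.phase):
        for k in harmonics:
            cols.append(np.sin(k * ph))
            cols.append(np.cos(k * ph))
    return np.column_stack(cols)


def dynamic_retroicor(ts: ROITimeseries, cardiac: PhaseSeries, resp: PhaseSeries,
                      cfg: SlidingGLMConfig = SlidingGLMConfig()) -> ROITimeseries:
    """Remove drifting cardiac/respiratory harmonics from one ROI trace.

    In each sliding window an OLS fit of sin/cos of the phase harmonics (plus
    an intercept and, by default, a linear drift term) is computed.  The
    physiological betas are attached to the window center, linearly
    interpolated across every sample (held constant beyond the first/last
    center), and the implied physiological waveform is subtracted.  The
    intercept and drift are nuisance terms of the regression only and are not
    removed from the data.  Output has the same length and grid as the input.
    """
    y = ts.values
    t = ts.times
    n = y.size
    if cardiac.phase.size != n or resp.phase.size != n:
        raise InvalidConfigError("phase series must be on the ROI sampling grid")
    X_phys = _phase_regressors(cardiac, resp, cfg.harmonics)
    n_phys = X_phys.shape[1]

    win_n = int(round(cfg.window / ts.tr))
    step_n = max(int(round(cfg.step / ts.tr)), 1)
    if win_n >= n:
        logger.info("series (%d samples) shorter than one %.0f s window; "
                    "using a single full-length window", n, cfg.window)
        starts = [0]
        win_n = n
    else:
        starts = list(range(0, n - win_n + 1, step_n))
        if starts[-1] != n - win_n:
            starts.append(n - win_n)

    centers = np.empty(len(starts))
    betas = np.empty((len(starts), n_phys))
    for i, s0 in enumerate(starts):
        sl = slice(s0, s0 + win_n)
        cols = [X_phys[sl], np.ones((win_n, 1))]
        if cfg.include_drift:
            cols.append(np.linspace(-1, 1, win_n)[:, None])
        X = np.hstack(cols)
        beta, *_ = np.linalg.lstsq(X, y[sl], rcond=None)
        betas[i] = beta[:n_phys]
        centers[i] = t[s0] + (win_n - 1) * ts.tr / 2.0

    if len(starts) == 1:
        beta_t = np.repeat(betas, n, axis=0)
    else:
        beta_t = np.column_stack(
            [np.interp(t, centers, betas[:, j]) for j in range(n_phys)]
        )
    fitted = np.sum(beta_t * X_phys, axis=1)
    return ROITimeseries(name=ts.name, series=ts.series.with_values(y - fitted), tr=ts.tr)


def static_retroicor(ts: ROITimeseries, cardiac: PhaseSeries, resp: PhaseSeries,
                     harmonics=(1, 2), include_drift: bool = True) -> ROITimeseries:
    """Single-window RETROICOR: one OLS fit over the whole run.

    The classical fixed-beta variant, kept as the comparison baseline for the
    sliding-window cleaner on drifting-frequency contamination.
    """
    cfg = SlidingGLMConfig(window=1e18, step=1e18, harmonics=tuple(harmonics),
                           include_drift=include_drift)
    return dynamic_retroicor(ts, cardiac, resp, cfg)


def amplitude_envelope(series: SampledSeries, band: tuple[float, float]) -> SampledSeries:
    """Band-limited instantaneous amplitude: band-pass then |analytic signal|."""
    lo, hi = band
    if hi >= series.rate / 2:
        raise InvalidConfigError(
            f"band top {hi} Hz exceeds Nyquist {series.rate / 2} Hz")
    if lo <= 0 or lo >= hi:
        raise InvalidConfigError(f"invalid band {band}")
    filtered = _fir_bandpass(series.values, series.rate, band)
    return series.with_values(np.abs(signal.hilbert(filtered)))
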