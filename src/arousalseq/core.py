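"""Core containers and exceptions shared across the pipeline.

The analysis operates on uniformly sampled scalar series (region-of-interest
mean BOLD traces, band-power traces, amplitude envelopes).  ``SampledSeries``
is the single in-memory representation for all of them: a value array plus a
start time and a sampling interval, from which a time axis is derived on
demand.  ``ROITimeseries`` wraps a series with a region name and its
repetition time (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ArousalSeqError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ArousalSeqError, ValueError):
    """A configuration value violates its documented constraint."""


class InvalidScheduleError(ArousalSeqError, ValueError):
    """An event schedule is inconsistent (overlapping responsive periods)."""


class FormatError(ArousalSeqError, ValueError):
    """An input table does not have the expected layout."""


class CoverageError(ArousalSeqError, ValueError):
    """A requested window falls outside the available data."""


class DegenerateSignalError(ArousalSeqError, ValueError):
    """A signal is constant or zero where structure is required."""


class DegenerateCorrelationError(DegenerateSignalError):
    """Cross-correlation undefined: zero variance at every admissible shift."""


class NoPositivePeakError(ArousalSeqError, ValueError):
    """Positive-restricted cross-correlation found no positive values."""


class InsufficientSignalError(ArousalSeqError, ValueError):
    """Too little data to estimate the requested quantity."""


class EmptyEnsembleError(ArousalSeqError, ValueError):
    """No valid events remained after window clipping and exclusions."""


class UnstableEstimateError(ArousalSeqError, RuntimeError):
    """Bootstrap failed in too many resamples to report an interval."""


class FitFailureError(ArousalSeqError, RuntimeError):
    """Model fitting did not converge in any restart."""

    def __init__(self, message: str, best_effort=None):
        super().__init__(message)
        self.best_effort = best_effort


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : ndarray
        Sample values (a.u.).
    start : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds; must be positive.
    """

    values: np.ndarray
    start: float = 0.0
    dt: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise InvalidConfigError(f"sampling interval must be positive, got {self.dt}")
        if self.values.ndim != 1:
            raise FormatError("SampledSeries values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n)

    @property
    def end(self) -> float:
        return self.start + self.dt * (self.n - 1)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def with_values(self, values: np.ndarray) -> "SampledSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class ROITimeseries:
    """One region's mean BOLD trace with its repetition time."""

    name: str
    series: SampledSeries
    tr: float = field(default=0.0)

    def __post_init__(self):
        if self.tr == 0.0:
            object.__setattr__(self, "tr", self.series.dt)

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def times(self) -> np.ndarray:
        return self.series.times
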