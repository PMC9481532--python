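"""Behavioral arousal detection from button-press logs.

Participants press a button on every breath while awake; silence marks
unresponsiveness.  A behavioral arousal is the first press after at least
20 s of unresponsiveness.  Arousals are classified by how long behavior is
subsequently maintained: counting the triggering press itself, a response
train of >= 5 presses before the next >= 20 s silence is *sustained*, <= 2 is
*transient*, and 3-4 presses fall in an *intermediate* band excluded from the
two-class comparison.  Arousal windows contaminated by head motion
(framewise displacement above 0.3 mm anywhere in the window) are flagged for
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CoverageError, FormatError, InvalidConfigError

SUSTAINED_MIN = 5
TRANSIENT_MAX = 2


@dataclass(frozen=True)
class ButtonPressLog:
    """Button-press onsets within one run."""

    presses: np.ndarray  # seconds, ascending
    run_start: float
    run_end: float

    def __post_init__(self):
        p = np.asarray(self.presses, dtype=float)
        object.__setattr__(self, "presses", p)
        if p.size and (np.any(np.diff(p) < 0)):
            raise FormatError("press times must be sorted ascending")
        if p.size and (p[0] < self.run_start or p[-1] > self.run_end):
            raise FormatError("press times must lie within [run_start, run_end]")


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume framewise displacement (mm) at the BOLD TR."""

    fd: np.ndarray
    tr: float
    start: float = 0.0

    def __post_init__(self):
        fd = np.asarray(self.fd, dtype=float)
        object.__setattr__(self, "fd", fd)
        if np.any(fd < 0):
            raise FormatError("framewise displacement must be non-negative")
        if self.tr <= 0:
            raise InvalidConfigError("TR must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start + self.tr * np.arange(self.fd.size)


@dataclass(frozen=True)
class ArousalEvent:
    """A detected transition from unresponsiveness to behavior."""

    time: float
    preceding_gap: float
    n_responses: int  # includes the triggering press
    label: str  # sustained | transient | intermediate
    excluded_by_motion: bool = False
    subject: str | None = None


def classify_count(n_responses: int) -> str:
    """Map a response-train length to its arousal class."""
    if n_responses >= SUSTAINED_MIN:
        return "sustained"
    if n_responses <= TRANSIENT_MAX:
        return "transient"
    return "intermediate"


def framewise_displacement(params: np.ndarray, tr: float, rotation_radius_mm: float = 50.0,
                           start: float = 0.0) -> MotionTrace:
    """Framewise displacement from 6 rigid-body parameters per volume.

    FD_t = sum |Delta translation| + radius * sum |Delta rotation|, with the
    three translations in mm, the three rotations in radians, and rotations
    converted to arc length on a 50 mm sphere.  The first volume has FD 0.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise FormatError(f"expected 6 motion columns, got shape {params.shape}")
    if params.shape[0] < 2:
        raise FormatError("need at least two volumes for framewise displacement")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return MotionTrace(fd=np.concatenate([[0.0], fd]), tr=tr, start=start)


def detect_arousals(log: ButtonPressLog, min_gap: float = 20.0) -> list[ArousalEvent]:
    """Find behavioral arousals: first press after >= ``min_gap`` of silence.

    Silence from the run start counts toward the gap, since unresponsiveness
    rather than a prior press is the defining condition.  The response count
    attached to each arousal includes the triggering press and every
    subsequent press before the next >= ``min_gap`` silence.
    """
    p = log.presses
    if p.size == 0:
        return []
    prev = np.concatenate([[log.run_start], p[:-1]])
    gaps = p - prev
    is_arousal = gaps >= min_gap
    idx = np.flatnonzero(is_arousal)
    events: list[ArousalEvent] = []
    for i in idx:
        # count presses in the train: up to (not incl.) the next arousal press
        j = i + 1
        while j < p.size and not is_arousal[j]:
            j += 1
        n = j - i
        events.append(
            ArousalEvent(
                time=float(p[i]),
                preceding_gap=float(gaps[i]),
                n_responses=n,
                label=classify_count(n),
            )
        )
    return events


def classify(event: ArousalEvent, log: ButtonPressLog | None = None) -> str:
    """Return the arousal class implied by the event's response count."""
    return classify_count(event.n_responses)


def apply_motion_exclusion(events: list[ArousalEvent], motion: MotionTrace,
                           threshold: float = 0.3, window: tuple[float, float] = (-10.0, 20.0),
                           ) -> list[ArousalEvent]:
    """Flag events whose window contains FD above ``threshold`` mm.

    Windows are clipped at the run edges; a window lying entirely outside the
    motion trace raises :class:`CoverageError`.
    """
    lo, hi = window
    t = motion.times
    out = []
    for ev in events:
        a, b = ev.time + lo, ev.time + hi
        mask = (t >= a) & (t <= b)
        if not mask.any():
            raise CoverageError(
                f"event at {ev.time:.2f}s: window [{a:.2f}, {b:.2f}]s outside motion trace"
            )
        excluded = bool(np.max(motion.fd[mask]) > threshold)
        out.append(replace(ev, excluded_by_motion=excluded))
    return out


def split_by_class(events: list[ArousalEvent]) -> tuple[list[ArousalEvent], list[ArousalEvent]]:
    """Partition into (sustained, transient); intermediates are dropped."""
    sustained = [e for e in events if e.label == "sustained"]
    transient = [e for e in events if e.label == "transient"]
    return sustained, transient
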