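"""Synthetic fast-fMRI sessions with recorded ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream estimator can be validated against known truth:

* per-ROI BOLD traces built as baseline drift + arousal-locked double-
  Gaussian responses (per-ROI amplitude and true lag) + quasi-periodic
  cardiac/respiratory contamination with a drifting fundamental (first and
  second harmonics) + white or AR(1) noise; cortical-type ROIs additionally
  carry a delayed negative (deactivation) component;
* button-press logs with pre-arousal quiescence and sustained / transient /
  intermediate response trains at roughly twice the breathing rate;
* pulse and respiration waveforms whose instantaneous frequency follows the
  configured trajectories;
* motion parameter traces with optional spikes;
* an optional EEG-like channel whose 10 Hz (alpha) amplitude rises after
  each arousal;
* breathhold sessions (27 s free / three 6 s paced breaths / 15 s hold,
  repeated) whose post-release responses are delayed per-ROI by a configured
  vascular delay.

One session seed spawns independent child seeds per component, so e.g. the
noise draw does not change when the motion model is reconfigured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .behavior import ButtonPressLog, MotionTrace, framewise_displacement
from .core import (
    InvalidConfigError,
    InvalidScheduleError,
    ROITimeseries,
    SampledSeries,
)
from .hrf import HRFParams, model_values
from .physio import CARDIAC_BAND, RESPIRATORY_BAND, PhysioRecording

#: canonical generative response: positive Gaussian peaking 6 s after the
#: effective onset (width 2 s) with a small later undershoot
CANONICAL_HRF = HRFParams(a1=1.0, mu1=6.0, sigma1=2.0, a2=-0.25, mu2=13.0, sigma2=3.0)
#: deactivation component for cortical-type ROIs: delayed negative Gaussian
CANONICAL_DEACTIVATION = HRFParams(a1=-1.0, mu1=11.0, sigma1=4.0)

THALAMIC_NUCLEI = ("CM", "VPL", "VLP", "MD", "PUL", "LGN", "VLA", "AV", "VA")

MIN_QUIESCENCE = 20.0


@dataclass(frozen=True)
class ROISpec:
    """Generative description of one region's arousal response."""

    name: str
    kind: str = "thalamic"  # thalamic | cortical
    lag: float = 0.0  # s relative to the nominal response; negative = early
    amplitude: float = 1.0
    hrf: HRFParams = CANONICAL_HRF
    deactivation_amplitude: float = 0.0  # scales CANONICAL_DEACTIVATION
    deactivation_delay: float = 5.0
    vascular_delay: float = 0.0  # breathhold-response delay, s


@dataclass
class GroundTruth:
    """Everything the analysis later estimates, stored at generation time."""

    lags: dict[str, float]
    amplitudes: dict[str, float]
    hrf_params: dict[str, HRFParams]
    arousal_times: np.ndarray
    arousal_classes: tuple[str, ...]
    cardiac_freq: tuple[float, float]
    respiratory_freq: tuple[float, float]
    noise_std: float
    seed: int
    vascular_delays: dict[str, float] = field(default_factory=dict)
    release_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        at = np.asarray(self.arousal_times, float)
        if at.size > 1:
            gaps = np.diff(at)
            if np.any(gaps <= MIN_QUIESCENCE):
                raise InvalidScheduleError(
                    f"arousal times must be separated by more than {MIN_QUIESCENCE} s")
        self.arousal_times = at
        for band, traj, label in ((CARDIAC_BAND, self.cardiac_freq, "cardiac"),
                                  (RESPIRATORY_BAND, self.respiratory_freq, "respiratory")):
            for f in traj:
                if not band[0] <= f <= band[1]:
                    raise InvalidConfigError(
                        f"{label} frequency {f} Hz outside band {band}")

    def to_dict(self) -> dict:
        return {
            "lags": self.lags,
            "amplitudes": self.amplitudes,
            "hrf_params": {k: v.as_array().tolist() for k, v in self.hrf_params.items()},
            "arousal_times": self.arousal_times.tolist(),
            "arousal_classes": list(self.arousal_classes),
            "cardiac_freq": list(self.cardiac_freq),
            "respiratory_freq": list(self.respiratory_freq),
            "noise_std": self.noise_std,
            "seed": self.seed,
            "vascular_delays": self.vascular_delays,
            "release_times": self.release_times.tolist(),
        }


@dataclass
class SyntheticSession:
    """A complete generated session and its ground truth."""

    rois: list[ROITimeseries]
    button_log: ButtonPressLog
    motion_params: np.ndarray  # volumes x 6
    physio: PhysioRecording | None
    eeg: SampledSeries | None
    truth: GroundTruth
    tr: float
    contamination: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def motion(self) -> MotionTrace:
        return framewise_displacement(self.motion_params, self.tr)

    @property
    def roi_dict(self) -> dict[str, ROITimeseries]:
        return {r.name: r for r in self.rois}


@dataclass(frozen=True)
class SessionConfig:
    """Generator settings; defaults reproduce the study conditions.

    TR defaults to the 7 T fast-fMRI sampling (0.247 s).  ``noise_std`` is in
    units of the unit response amplitude, so 0.2 gives single-event SNR 5.
    """

    tr: float = 0.247
    duration: float = 600.0
    seed: int = 0
    rois: tuple[ROISpec, ...] | None = None
    n_thalamic: int = 9
    n_cortical: int = 0
    arousal_times: tuple[float, ...] | None = None
    arousal_classes: tuple[str, ...] | None = None
    n_arousals: int | None = None
    noise_std: float = 0.2
    ar1: float = 0.0
    drift_amplitude: float = 0.05
    cardiac_freq: tuple[float, float] = (0.9, 1.3)
    respiratory_freq: tuple[float, float] = (0.2, 0.3)
    cardiac_amp: float = 0.0
    respiratory_amp: float = 0.0
    breath_rate: float = 0.25
    motion_spike_times: tuple[float, ...] = ()
    motion_noise_mm: float = 0.005
    with_eeg: bool = False
    eeg_fs: float = 200.0
    physio_fs: float = 100.0

    def __post_init__(self):
        if self.tr <= 0:
            raise InvalidConfigError(f"TR must be positive, got {self.tr}")
        if self.duration <= 0:
            raise InvalidConfigError(f"duration must be positive, got {self.duration}")
        if self.duration < 300:
            raise InvalidConfigError("sessions shorter than 300 s are not supported")
        n_rois = len(self.rois) if self.rois is not None else self.n_thalamic + self.n_cortical
        if n_rois < 1:
            raise InvalidConfigError("at least one ROI required")


def default_rois(n_thalamic: int = 9, n_cortical: int = 30,
                 lag_span: float = 2.1) -> tuple[ROISpec, ...]:
    """The study-like ROI set: 9 thalamic nuclei with lags spanning 2.1 s
    (CM earliest, VA latest) and cortical regions with post-arousal
    deactivation."""
    specs = []
    if n_thalamic > 0:
        lags = (np.linspace(-lag_span / 2, lag_span / 2, n_thalamic)
                if n_thalamic > 1 else np.zeros(1))
        names = (THALAMIC_NUCLEI if n_thalamic == len(THALAMIC_NUCLEI)
                 else tuple(f"thal_{i:02d}" for i in range(n_thalamic)))
        for name, lag in zip(names, lags):
            specs.append(ROISpec(name=name, kind="thalamic", lag=float(lag)))
    for i in range(n_cortical):
        specs.append(
            ROISpec(name=f"ctx_{i:02d}", kind="cortical", lag=0.0, amplitude=0.3,
                    deactivation_amplitude=1.0)
        )
    return tuple(specs)


def schedule_arousals(duration: float, n: int, rng: np.random.Generator,
                      min_spacing: float = 50.0, lead_in: float = 40.0,
                      tail: float = 30.0) -> np.ndarray:
    """Arousal times with quiescence before each event and room for windows."""
    usable = duration - lead_in - tail
    if n < 1 or usable < (n - 1) * min_spacing:
        raise InvalidScheduleError(
            f"cannot fit {n} arousals spaced >= {min_spacing} s in {duration} s")
    slack = usable - (n - 1) * min_spacing
    offsets = np.sort(rng.uniform(0, slack, n))
    return lead_in + offsets + min_spacing * np.arange(n)


def _class_counts(label: str, rng: np.random.Generator) -> int:
    if label == "sustained":
        return int(rng.integers(5, 11))
    if label == "transient":
        return int(rng.integers(1, 3))
    if label == "intermediate":
        return int(rng.integers(3, 5))
    raise InvalidConfigError(f"unknown arousal class {label!r}")


def make_button_log(arousal_times, classes, breath_rate: float = 0.25,
                    run_start: float = 0.0, run_end: float | None = None,
                    seed: int = 0, press_counts=None) -> ButtonPressLog:
    """Button presses: each arousal starts a train at ~2x the breathing rate.

    The first press of each train is at the arousal time; subsequent presses
    follow at jittered intervals of 1 / (2 * breath_rate).  Trains must end
    at least 20 s before the next arousal (otherwise the next event would not
    qualify as an arousal) — violating schedules raise
    :class:`InvalidScheduleError`.
    """
    if not RESPIRATORY_BAND[0] <= breath_rate <= RESPIRATORY_BAND[1]:
        raise InvalidConfigError(
            f"breath rate {breath_rate} Hz outside {RESPIRATORY_BAND}")
    rng = np.random.default_rng(seed)
    at = np.asarray(arousal_times, float)
    classes = tuple(classes)
    if at.size != len(classes):
        raise InvalidConfigError("one class per scheduled arousal required")
    interval = 1.0 / (2.0 * breath_rate)
    presses = []
    train_ends = []
    for i, (t0, label) in enumerate(zip(at, classes)):
        n = press_counts[i] if press_counts is not None else _class_counts(label, rng)
        gaps = interval * rng.uniform(0.85, 1.15, max(n - 1, 0))
        train = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        presses.append(train)
        train_ends.append(train[-1])
    for i in range(at.size - 1):
        if at[i + 1] - train_ends[i] < MIN_QUIESCENCE:
            raise InvalidScheduleError(
                f"response train after arousal {i} overlaps the quiescence "
                f"required before arousal {i + 1}")
    all_presses = np.concatenate(presses) if presses else np.empty(0)
    if run_end is None:
        run_end = (all_presses[-1] if all_presses.size else run_start) + MIN_QUIESCENCE
    if all_presses.size and all_presses[-1] > run_end:
        raise InvalidScheduleError("response train extends past the run end")
    return ButtonPressLog(presses=all_presses, run_start=run_start, run_end=run_end)


def _phase_from_trajectory(freq: tuple[float, float], t: np.ndarray) -> np.ndarray:
    """Integrated phase of a linearly drifting instantaneous frequency."""
    f0, f1 = freq
    if t.size == 0:
        return t
    inst = f0 + (f1 - f0) * (t - t[0]) / max(t[-1] - t[0], 1e-12)
    dt = np.diff(t, prepend=t[0])
    return 2 * np.pi * np.cumsum(inst * dt)


def make_physio(cardiac_freq=(0.9, 1.3), respiratory_freq=(0.2, 0.3), fs: float = 100.0,
                duration: float = 600.0, seed: int = 0, noise_std: float = 0.02,
                start: float = 0.0) -> PhysioRecording:
    """Pulse and respiration waveforms following the frequency trajectories.

    The pulse channel is a sharp periodic bump (von Mises shape in phase, one
    peak per cardiac cycle); respiration is a smooth sinusoid.  Both carry
    additive Gaussian noise.
    """
    for band, traj, label in ((CARDIAC_BAND, cardiac_freq, "cardiac"),
                              (RESPIRATORY_BAND, respiratory_freq, "respiratory")):
        for f in traj:
            if not band[0] <= f <= band[1]:
                raise InvalidConfigError(f"{label} frequency {f} Hz outside band {band}")
    if fs < 20:
        raise InvalidConfigError("physio sampling rate must be >= 20 Hz")
    rng = np.random.default_rng(seed)
    t = start + np.arange(int(round(duration * fs))) / fs
    phi_c = _phase_from_trajectory(tuple(cardiac_freq), t)
    phi_r = _phase_from_trajectory(tuple(respiratory_freq), t)
    cardiac = np.exp(8.0 * (np.cos(phi_c) - 1.0))  # pulse-like bump per cycle
    respiratory = np.sin(phi_r)
    if noise_std > 0:
        cardiac = cardiac + rng.normal(0, noise_std, t.size)
        respiratory = respiratory + rng.normal(0, noise_std, t.size)
    return PhysioRecording(cardiac=cardiac, respiratory=respiratory, fs=fs, start=start)


def _ar1_noise(n: int, std: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if std <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, std, n)
    if rho == 0:
        return white
    out = np.empty(n)
    out[0] = white[0]
    innov_std = np.sqrt(1 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov_std * white[i]
    return out


def _add_local(trace: np.ndarray, t: np.ndarray, tr: float, center: float,
               params: HRFParams, amplitude: float) -> None:
    """Add amplitude * model(t - center) on its local support only."""
    if amplitude == 0.0:
        return
    lo = center - 15.0
    hi = center + max(params.mu1, params.mu2) + 6 * max(params.sigma1, params.sigma2)
    i0 = max(int(np.floor((lo - t[0]) / tr)), 0)
    i1 = min(int(np.ceil((hi - t[0]) / tr)) + 1, t.size)
    if i1 <= i0:
        return
    trace[i0:i1] += amplitude * model_values(params, t[i0:i1] - center)


def make_session(config: SessionConfig) -> SyntheticSession:
    """Generate a full synthetic session from one config.

    Deterministic for a fixed seed: the session seed spawns child seeds for
    the schedule, button log, per-ROI noise, physio, motion and EEG, so each
    component is independently reproducible.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (ss_sched, ss_press, ss_noise, ss_physio, ss_motion,
     ss_eeg, ss_classes) = root.spawn(7)

    rois = cfg.rois if cfg.rois is not None else default_rois(cfg.n_thalamic, cfg.n_cortical)
    n_samples = int(round(cfg.duration / cfg.tr))
    t = cfg.tr * np.arange(n_samples)

    # --- arousal schedule and classes
    if cfg.arousal_times is not None:
        arousal_times = np.asarray(cfg.arousal_times, float)
    else:
        n_events = cfg.n_arousals if cfg.n_arousals is not None else max(
            int((cfg.duration - 70) // 50), 1)
        arousal_times = schedule_arousals(cfg.duration, n_events,
                                          np.random.default_rng(ss_sched))
    if cfg.arousal_classes is not None:
        classes = tuple(cfg.arousal_classes)
        if len(classes) != arousal_times.size:
            raise InvalidConfigError("one class per arousal required")
    else:
        rng_c = np.random.default_rng(ss_classes)
        classes = tuple(
            rng_c.choice(["sustained", "transient", "intermediate"], p=[0.45, 0.35, 0.2])
            for _ in range(arousal_times.size)
        )

    # --- button log
    log = make_button_log(arousal_times, classes, cfg.breath_rate,
                          run_start=0.0, run_end=cfg.duration,
                          seed=int(ss_press.generate_state(1)[0] % 2**31))

    # --- physiological contamination evaluated on the BOLD grid
    phi_c = _phase_from_trajectory(cfg.cardiac_freq, t)
    phi_r = _phase_from_trajectory(cfg.respiratory_freq, t)
    base_contam = None
    if cfg.cardiac_amp > 0 or cfg.respiratory_amp > 0:
        base_contam = (
            cfg.cardiac_amp * (np.sin(phi_c) + 0.5 * np.sin(2 * phi_c))
            + cfg.respiratory_amp * (np.sin(phi_r) + 0.5 * np.sin(2 * phi_r))
        )

    # --- per-ROI traces
    rng_noise = np.random.default_rng(ss_noise)
    traces: list[ROITimeseries] = []
    contamination: dict[str, np.ndarray] = {}
    for spec in rois:
        trace = np.zeros(n_samples)
        if cfg.drift_amplitude > 0:
            f_drift = rng_noise.uniform(0.003, 0.008)
            trace += cfg.drift_amplitude * np.sin(
                2 * np.pi * f_drift * t + rng_noise.uniform(0, 2 * np.pi))
        for at in arousal_times:
            _add_local(trace, t, cfg.tr, at + spec.lag, spec.hrf, spec.amplitude)
            if spec.kind == "cortical" and spec.deactivation_amplitude != 0:
                _add_local(trace, t, cfg.tr, at + spec.deactivation_delay,
                           CANONICAL_DEACTIVATION, spec.deactivation_amplitude)
        if base_contam is not None:
            scale = rng_noise.uniform(0.7, 1.3)
            contam = scale * base_contam
            contamination[spec.name] = contam
            trace = trace + contam
        trace = trace + _ar1_noise(n_samples, cfg.noise_std, cfg.ar1, rng_noise)
        traces.append(ROITimeseries(
            name=spec.name, series=SampledSeries(trace, start=0.0, dt=cfg.tr), tr=cfg.tr))

    # --- physio recording
    physio = make_physio(cfg.cardiac_freq, cfg.respiratory_freq, cfg.physio_fs,
                         cfg.duration, seed=int(ss_physio.generate_state(1)[0] % 2**31))

    # --- motion parameters with optional spikes
    rng_m = np.random.default_rng(ss_motion)
    motion = rng_m.normal(0.0, cfg.motion_noise_mm, (n_samples, 6))
    motion[:, 3:] *= 1e-3  # rotations (rad) small relative to translations
    motion = np.cumsum(motion, axis=0) * 0.05  # slow random walk
    for spike_t in cfg.motion_spike_times:
        i = int(round(spike_t / cfg.tr))
        if 0 <= i < n_samples:
            motion[i:, 0] += 0.5  # 0.5 mm translation step
    # --- EEG-like channel: alpha amplitude rises after each arousal
    eeg = None
    if cfg.with_eeg:
        rng_e = np.random.default_rng(ss_eeg)
        n_e = int(round(cfg.duration * cfg.eeg_fs))
        te = np.arange(n_e) / cfg.eeg_fs
        from scipy.special import expit

        alpha_env = np.full(n_e, 0.2)
        for at in arousal_times:
            rise = expit((te - at) / 0.5)
            fall = expit(-(te - at - 15.0) / 2.0)
            alpha_env += 1.3 * rise * fall
        sig = alpha_env * np.sin(2 * np.pi * 10.0 * te + rng_e.uniform(0, 2 * np.pi))
        sig = sig + rng_e.normal(0, 0.5, n_e)
        eeg = SampledSeries(sig, start=0.0, dt=1.0 / cfg.eeg_fs)

    truth = GroundTruth(
        lags={s.name: s.lag for s in rois},
        amplitudes={s.name: s.amplitude for s in rois},
        hrf_params={s.name: s.hrf for s in rois},
        arousal_times=arousal_times,
        arousal_classes=classes,
        cardiac_freq=tuple(cfg.cardiac_freq),
        respiratory_freq=tuple(cfg.respiratory_freq),
        noise_std=cfg.noise_std,
        seed=cfg.seed,
        vascular_delays={s.name: s.vascular_delay for s in rois},
    )
    return SyntheticSession(rois=traces, button_log=log, motion_params=motion,
                            physio=physio, eeg=eeg, truth=truth, tr=cfg.tr,
                            contamination=contamination)


@dataclass(frozen=True)
class BreathholdConfig:
    """Breathhold protocol settings: 27 s free breathing, three paced breaths
    of 3 s in and 3 s out, then a 15 s hold, repeated ``n_cycles`` times."""

    tr: float = 0.247
    n_cycles: int = 8
    free_s: float = 27.0
    paced_s: float = 18.0
    hold_s: float = 15.0
    seed: int = 0
    rois: tuple[ROISpec, ...] = ()
    response_amplitude: float = 1.0
    noise_std: float = 0.0
    tail_s: float = 40.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise InvalidConfigError("need at least one breathhold cycle")
        if self.tr <= 0:
            raise InvalidConfigError("TR must be positive")

    @property
    def cycle_s(self) -> float:
        return self.free_s + self.paced_s + self.hold_s

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_s + self.tail_s


#: breathhold-release response: vasodilation peak ~8 s after release
BREATHHOLD_HRF = HRFParams(a1=1.0, mu1=8.0, sigma1=3.0)


def make_breathhold_session(config: BreathholdConfig) -> SyntheticSession:
    """Generate a breathhold run: post-release responses delayed per ROI.

    Each ROI's response to every breathhold release is the canonical
    release response shifted by the ROI's ``vascular_delay``; release times
    are recorded in the ground truth and in the returned event log.
    """
    cfg = config
    rois = cfg.rois if cfg.rois else default_rois(9, 0)
    root = np.random.SeedSequence(cfg.seed)
    ss_noise, ss_motion = root.spawn(2)
    n_samples = int(round(cfg.duration / cfg.tr))
    t = cfg.tr * np.arange(n_samples)
    releases = cfg.cycle_s * np.arange(1, cfg.n_cycles + 1)

    rng = np.random.default_rng(ss_noise)
    traces = []
    for spec in rois:
        trace = np.zeros(n_samples)
        amp = cfg.response_amplitude * spec.amplitude
        for rel in releases:
            _add_local(trace, t, cfg.tr, rel + spec.vascular_delay, BREATHHOLD_HRF, amp)
        trace = trace + _ar1_noise(n_samples, cfg.noise_std, 0.0, rng)
        traces.append(ROITimeseries(
            name=spec.name, series=SampledSeries(trace, start=0.0, dt=cfg.tr), tr=cfg.tr))

    rng_m = np.random.default_rng(ss_motion)
    motion = np.cumsum(rng_m.normal(0.0, 0.002, (n_samples, 6)), axis=0) * 0.05
    motion[:, 3:] *= 1e-3

    truth = GroundTruth(
        lags={s.name: s.lag for s in rois},
        amplitudes={s.name: s.amplitude for s in rois},
        hrf_params={s.name: BREATHHOLD_HRF for s in rois},
        arousal_times=np.empty(0),
        arousal_classes=(),
        cardiac_freq=(1.0, 1.0),
        respiratory_freq=(0.25, 0.25),
        noise_std=cfg.noise_std,
        seed=cfg.seed,
        vascular_delays={s.name: s.vascular_delay for s in rois},
        release_times=releases,
    )
    log = ButtonPressLog(presses=np.empty(0), run_start=0.0, run_end=cfg.duration)
    return SyntheticSession(rois=traces, button_log=log, motion_params=motion,
                            physio=None, eeg=None, truth=truth, tr=cfg.tr)


def make_locked_cohort(n_subjects: int, events_per_subject: int,
                       roi_specs: tuple[ROISpec, ...] | None = None,
                       tr: float = 0.247, upsample_factor: int = 4,
                       pre: float = 10.0, post: float = 20.0,
                       noise_std: float = 0.2, seed: int = 0,
                       between_subject_lag_sd: float = 0.0):
    """Directly generate arousal-locked ensembles for estimator studies.

    Builds per-ROI event x time matrices on the upsampled grid without
    simulating a whole run: each row is the ROI's lagged response plus
    independent noise.  ``between_subject_lag_sd`` adds a subject- and
    ROI-specific lag offset (drawn once per subject x ROI), emulating
    between-subject variability in each region's relative timing.  Returns
    ``(ensembles, truth_lags)`` where ensembles carry per-row subject ids
    for hierarchical resampling.
    """
    from .locked import LockedEnsemble  # local import to avoid a cycle

    if roi_specs is None:
        roi_specs = default_rois(9, 0)
    step = tr / upsample_factor
    n_pre, n_post = int(round(pre / step)), int(round(post / step))
    times = (np.arange(n_pre + n_post + 1) - n_pre) * step
    rng = np.random.default_rng(seed)
    n_total = n_subjects * events_per_subject
    subjects = tuple(f"sub-{i:02d}" for i in range(n_subjects)
                     for _ in range(events_per_subject))
    subj_jitter = (rng.normal(0.0, between_subject_lag_sd,
                              (n_subjects, len(roi_specs)))
                   if between_subject_lag_sd > 0
                   else np.zeros((n_subjects, len(roi_specs))))
    ensembles = {}
    for j, spec in enumerate(roi_specs):
        rows = np.empty((n_total, times.size))
        for i in range(n_total):
            jit = subj_jitter[i // events_per_subject, j]
            rows[i] = spec.amplitude * model_values(spec.hrf, times - spec.lag - jit)
        # noise at the acquisition grid, linearly upsampled like real data
        if noise_std > 0:
            n_orig = int(np.ceil((times.size - 1) / upsample_factor)) + 1
            coarse = rng.normal(0.0, noise_std, (n_total, n_orig))
            fine_idx = np.arange(times.size) / upsample_factor
            rows += np.vstack([np.interp(fine_idx, np.arange(n_orig), c) for c in coarse])
        ensembles[spec.name] = LockedEnsemble(matrix=rows, times=times, subjects=subjects)
    return ensembles, {s.name: s.lag for s in roi_specs}


def write_session(session: SyntheticSession, outdir, provenance=None) -> None:
    """Serialize a session: ROI table, events, motion, physio, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = dict(provenance or {})
    prov.setdefault("seed", session.truth.seed)
    _io.write_roi_table(outdir / "roi_bold.tsv", session.rois, prov)
    log = session.button_log
    onsets = list(log.presses) + list(session.truth.release_times)
    types = ["press"] * log.presses.size + \
        ["breathhold_release"] * session.truth.release_times.size
    order = np.argsort(onsets) if onsets else []
    _io.write_events(outdir / "events.tsv", [onsets[i] for i in order],
                     [types[i] for i in order], provenance=prov)
    _io.write_motion(outdir / "motion.tsv", session.motion_params, session.tr, prov)
    if session.physio is not None:
        _io.write_physio(outdir / "physio.tsv", outdir / "physio.json",
                         session.physio.cardiac, session.physio.respiratory,
                         session.physio.fs, session.physio.start, prov)
    if session.eeg is not None:
        _io.write_tsv(outdir / "eeg.tsv",
                      pd.DataFrame({"time": session.eeg.times,
                                    "value": session.eeg.values}), prov)
    _io.write_json(outdir / "ground_truth.json", session.truth.to_dict(), prov)
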