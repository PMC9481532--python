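"""End-to-end orchestration: one config in, the headline tables out.

Stages run in the order the science requires: arousal detection from the
button log (with motion exclusion), dynamic physiological cleaning of the
ROI traces, arousal-locked ensembles (upsample, window, baseline-center),
latency estimates, cross-ROI lag sequencing with bootstrap CIs, HRF-onset
fits, the sustained/transient split, and — when an EEG channel is present —
the alpha-power pre/post confirmation.  Every output table carries a
provenance block (config hash, seed) and all stage intermediates are
written, so any stage can be audited or re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, hrf, io as _io, lags as lags_mod, locked, physio as physio_mod, spectral
from .core import ArousalSeqError, InvalidConfigError, SampledSeries
from .synth import SyntheticSession

logger = logging.getLogger(__name__)

# re-exported here because the class split drives the pipeline's per-class runs
split_by_class = behavior.split_by_class


@dataclass
class RunConfig:
    """All stage parameters with study defaults, plus input/output paths."""

    session_dir: str | None = None
    out_dir: str = "arousalseq_out"
    seed: int = 0
    min_gap: float = 20.0
    fd_threshold: float = 0.3
    window_pre: float = 10.0
    window_post: float = 20.0
    baseline: tuple[float, float] = (-10.0, -7.0)
    upsample: int = 4
    n_bootstrap: int = 1000
    hierarchical: bool = False
    target_total: int | None = None
    max_lag: float = 10.0
    clean_physio: bool = True
    glm_window: float = 1000.0
    glm_step: float = 400.0
    harmonics: tuple[int, ...] = (1, 2)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    onset_fraction: float = 0.1
    hrf_restarts: int = 8

    def digest(self) -> str:
        # hash analysis parameters only, not I/O locations
        d = {k: v for k, v in asdict(self).items()
             if k not in ("session_dir", "out_dir")}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.digest(), "seed": self.seed}


@dataclass
class ResultBundle:
    """Everything the pipeline computed, as in-memory objects."""

    events: list
    latencies: dict
    lag_estimates: dict
    sequence: object
    class_sequences: dict = field(default_factory=dict)
    onsets: dict = field(default_factory=dict)
    pca: object = None
    binned: dict = field(default_factory=dict)
    alpha_test: dict | None = None
    provenance: dict = field(default_factory=dict)


def load_session_dir(session_dir) -> dict:
    """Load the plain-text session layout written by the generator."""
    d = Path(session_dir)
    rois = _io.read_roi_table(d / "roi_bold.tsv")
    events = _io.read_events(d / "events.tsv")
    motion = _io.read_motion(d / "motion.tsv") if (d / "motion.tsv").exists() else None
    phys = None
    if (d / "physio.tsv").exists():
        c, r, fs, start = _io.read_physio(d / "physio.tsv", d / "physio.json")
        phys = physio_mod.PhysioRecording(cardiac=c, respiratory=r, fs=fs, start=start)
    eeg = None
    if (d / "eeg.tsv").exists():
        df = _io.read_tsv(d / "eeg.tsv")
        t = df["time"].to_numpy(float)
        eeg = SampledSeries(df["value"].to_numpy(float), start=float(t[0]),
                            dt=float(np.median(np.diff(t))))
    return {"rois": rois, "events": events, "motion": motion, "physio": phys, "eeg": eeg}


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except ArousalSeqError as err:
                raise type(err)(f"[stage {name}] {err}") from err
            logger.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_session(session: SyntheticSession, cfg: RunConfig,
                write: bool = False) -> ResultBundle:
    """Run the full analysis on an in-memory session."""
    data = {
        "rois": session.rois,
        "log": session.button_log,
        "motion_params": session.motion_params,
        "physio": session.physio,
        "eeg": session.eeg,
        "tr": session.tr,
    }
    return _run(data, cfg, write)


def run_all(cfg: RunConfig) -> ResultBundle:
    """Run the full analysis from a session directory on disk."""
    if cfg.session_dir is None:
        raise InvalidConfigError("RunConfig.session_dir is required for run_all")
    d = Path(cfg.session_dir)
    if not d.exists():
        raise InvalidConfigError(f"session directory not found: {d}")
    raw = load_session_dir(d)
    presses = raw["events"].query("trial_type == 'press'")["onset"].to_numpy(float)
    t0 = float(raw["rois"][0].series.start)
    t1 = float(raw["rois"][0].series.end)
    log = behavior.ButtonPressLog(presses=presses, run_start=t0, run_end=t1)
    data = {
        "rois": raw["rois"],
        "log": log,
        "motion_params": raw["motion"],
        "physio": raw["physio"],
        "eeg": raw["eeg"],
        "tr": raw["rois"][0].tr,
    }
    return _run(data, cfg, write=True)


@_stage("behavior")
def _detect(data, cfg):
    events = behavior.detect_arousals(data["log"], cfg.min_gap)
    if data["motion_params"] is not None and len(events):
        trace = behavior.framewise_displacement(data["motion_params"], data["tr"])
        events = behavior.apply_motion_exclusion(
            events, trace, cfg.fd_threshold, (-cfg.window_pre, cfg.window_post))
    return events


@_stage("physio")
def _clean(data, cfg):
    rois = data["rois"]
    rec = data["physio"]
    if rec is None or not cfg.clean_physio:
        return rois
    grid = rois[0].times
    card = physio_mod.cardiac_phase(rec, grid)
    resp = physio_mod.respiratory_phase(rec, grid)
    glm = physio_mod.SlidingGLMConfig(window=cfg.glm_window, step=cfg.glm_step,
                                      harmonics=cfg.harmonics)
    return [physio_mod.dynamic_retroicor(r, card, resp, glm) for r in rois]


@_stage("locked")
def _ensembles(rois, event_times, cfg, subjects=None):
    out = {}
    for roi in rois:
        up = locked.upsample(roi, cfg.upsample)
        ens = locked.extract_windows(up, event_times, cfg.window_pre, cfg.window_post,
                                     subjects=subjects)
        out[roi.name] = locked.baseline_center(ens, cfg.baseline)
    return out


def _run(data, cfg: RunConfig, write: bool) -> ResultBundle:
    prov = cfg.provenance()
    out = Path(cfg.out_dir)
    events = _detect(data, cfg)
    kept = [e for e in events if not e.excluded_by_motion]
    if not kept:
        raise InvalidConfigError("no arousals survived detection and motion exclusion")
    cleaned = _clean(data, cfg)
    ensembles = _ensembles(cleaned, [e.time for e in kept], cfg)

    # latencies (absolute polarity by default) per ROI
    latencies = {}
    for name, ens in ensembles.items():
        try:
            latencies[name] = locked.bootstrap_latency(
                ens, "absolute", cfg.n_bootstrap, cfg.seed, cfg.baseline)
        except ArousalSeqError as err:
            logger.warning("latency for %s skipped: %s", name, err)

    # lag sequence over all arousals
    if cfg.hierarchical:
        lag_est = lags_mod.hierarchical_bootstrap_lags(
            ensembles, cfg.target_total, cfg.n_bootstrap, cfg.seed, cfg.max_lag)
    else:
        lag_est = lags_mod.bootstrap_lags(
            ensembles, cfg.n_bootstrap, cfg.seed, cfg.max_lag)
    seq = lags_mod.sequence(lag_est) if len(lag_est) >= 2 else None

    # sustained / transient split; positive-correlation-restricted lags
    sustained, transient = split_by_class(kept)
    class_sequences = {}
    for label, evs in (("sustained", sustained), ("transient", transient)):
        if len(evs) < 2:
            logger.warning("class %s has %d arousals; skipped", label, len(evs))
            continue
        ens_c = _ensembles(cleaned, [e.time for e in evs], cfg)
        try:
            est_c = lags_mod.bootstrap_lags(ens_c, cfg.n_bootstrap, cfg.seed,
                                            cfg.max_lag, positive_only=True)
            class_sequences[label] = lags_mod.sequence(est_c)
        except ArousalSeqError as err:
            logger.warning("class %s lags skipped: %s", label, err)

    # HRF-onset fits per ROI
    onsets = {}
    for name, ens in ensembles.items():
        try:
            fit = hrf.fit(SampledSeries(
                ens.matrix.mean(axis=0), start=float(ens.times[0]), dt=ens.step),
                restarts=cfg.hrf_restarts, seed=cfg.seed,
                onset_fraction=cfg.onset_fraction)
            onsets[name] = fit
        except ArousalSeqError as err:
            logger.warning("HRF fit for %s skipped: %s", name, err)

    # PCA modes over all ROI means
    names = list(ensembles)
    means = np.vstack([ensembles[k].matrix.mean(axis=0) for k in names])
    pca = locked.pca_modes(means, ensembles[names[0]].times, cfg.baseline) \
        if len(names) >= 2 else None

    # binned one-sample tests per ROI
    binned = {name: locked.binned_test(ens, n_rois_tested=len(ensembles))
              for name, ens in ensembles.items()}

    # EEG alpha confirmation
    alpha_test = None
    if data.get("eeg") is not None:
        spec = spectral.multitaper_spectrogram(data["eeg"])
        power = spectral.band_power(spec, cfg.alpha_band)
        try:
            alpha_test = spectral.prepost_test(power, [e.time for e in kept])
        except ArousalSeqError as err:
            logger.warning("alpha pre/post test skipped: %s", err)

    bundle = ResultBundle(events=events, latencies=latencies, lag_estimates=lag_est,
                          sequence=seq, class_sequences=class_sequences, onsets=onsets,
                          pca=pca, binned=binned, alpha_test=alpha_test, provenance=prov)
    if write:
        _write_bundle(bundle, ensembles, out, prov)
    return bundle


def _lag_table(estimates) -> pd.DataFrame:
    rows = [{"roi": e.roi, "lag_s": e.lag, "r": e.r, "ci_lo": e.ci_lo, "ci_hi": e.ci_hi}
            for e in (estimates.values() if isinstance(estimates, dict) else estimates)]
    return pd.DataFrame(rows)


def _write_bundle(bundle: ResultBundle, ensembles, out: Path, prov: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _io.write_events(out / "arousals.tsv",
                     [e.time for e in bundle.events],
                     [f"arousal_{e.label}" for e in bundle.events],
                     provenance=prov)
    lat = pd.DataFrame(
        [{"roi": k, "latency_s": v.latency, "ci_lo": v.ci_lo, "ci_hi": v.ci_hi,
          "polarity": v.polarity} for k, v in bundle.latencies.items()])
    _io.write_tsv(out / "latencies.tsv", lat, prov)
    _io.write_tsv(out / "lags_all.tsv", _lag_table(bundle.lag_estimates), prov)
    if bundle.sequence is not None:
        _io.write_json(out / "sequence.json",
                       {"order": list(bundle.sequence.order),
                        "lag_range_s": bundle.sequence.lag_range}, prov)
    for label, seq in bundle.class_sequences.items():
        _io.write_tsv(out / f"lags_{label}.tsv", _lag_table(seq.estimates), prov)
    ons = pd.DataFrame(
        [{"roi": k, "onset_s": f.onset_time, "rmse": f.rmse,
          "max_amplitude": f.max_amplitude, "low_confidence": f.low_confidence}
         for k, f in bundle.onsets.items()])
    _io.write_tsv(out / "onsets.tsv", ons, prov)
    if bundle.pca is not None:
        _io.write_tsv(out / "pca_variance.tsv",
                      pd.DataFrame({"component": np.arange(
                          bundle.pca.variance_fractions.size) + 1,
                          "variance_fraction": bundle.pca.variance_fractions}), prov)
    names = list(ensembles)
    times = ensembles[names[0]].times
    mean_tab = {"time": times}
    for k in names:
        m, s = locked.ensemble_mean_sem(ensembles[k])
        mean_tab[k] = m
        mean_tab[f"{k}_sem"] = s
    _io.write_tsv(out / "locked_means.tsv", pd.DataFrame(mean_tab), prov)
    bt = []
    for name, res in bundle.binned.items():
        for c, p, sig in zip(res["bin_centers"], res["p_corrected"], res["significant"]):
            bt.append({"roi": name, "bin_center_s": c, "p_corrected": p, "significant": sig})
    _io.write_tsv(out / "binned_tests.tsv", pd.DataFrame(bt), prov)
    if bundle.alpha_test is not None:
        _io.write_json(out / "alpha_test.json",
                       {k: v for k, v in bundle.alpha_test.items()
                        if k in ("t", "p", "n_events", "significant")}, prov)
    _io.write_json(out / "provenance.json", prov)
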