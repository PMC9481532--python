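# Methods

`arousalseq` estimates the relative timing of arousal-locked BOLD activity
across brain regions from fast fMRI, together with the behavioral, physiological
and electrophysiological context of each arousal. This note documents the
models, the defaults and why they are what they are, the synthetic data the
package validates itself against, and the numerical choices that matter.

## The analysis model

**Behavioral arousal.** Participants press a button on every breath while
awake. An arousal is the first press after at least 20 s of silence
(`min_gap = 20 s`). The press train that follows — counting the triggering
press — classifies the arousal: ≥ 5 presses before the next ≥ 20 s silence
is *sustained*, ≤ 2 is *transient*, 3–4 is *intermediate* and excluded from
the two-class contrast. Silence from the run start counts toward the gap:
unresponsiveness, not a prior press, is the defining condition. Arousal
windows containing framewise displacement above 0.3 mm anywhere in
(−10, +20) s are excluded. FD is the Power convention,
FD_t = Σ|Δtranslation| + 50 mm · Σ|Δrotation|.

**Physiological cleaning.** Fast sampling (TR ≈ 0.25–0.37 s) resolves
cardiac and respiratory oscillations directly, so they contaminate ROI
traces as quasi-periodic components whose fundamental drifts over a
night-long session. The cleaner is RETROICOR-style regression with
time-varying betas: sin/cos of the first and second harmonics of the
cardiac phase (from pulse peaks, phase ramping 0→2π between beats) and the
respiratory phase (FIR band-pass 0.16–0.4 Hz, analytic-signal angle) are fit
by OLS in 1000 s windows sliding by 400 s; betas sit at window centers, are
linearly interpolated to every sample and held beyond the first/last
center; the implied physiological waveform is subtracted. An intercept and
a linear drift term per window are included (disableable) so slow trends do
not leak into the physiological betas; they are estimated, not subtracted.
Note that any regression-based cleaner also removes the finite-sample
projection of genuine signal onto the regressors; for transient responses
against 1000 s windows this is O(1e-4) of the signal amplitude.

**Locked ensembles and latency.** Traces are linearly upsampled 4× (61.75 ms
at TR 0.247 s) so windows align to within half an interpolated sample of
each arousal; rows span −10…+20 s and are centered to their mean over
−10…−7 s. The response latency is the *20% latency*: the earliest
post-baseline time at which the mean deviates from baseline by 20% of its
extremal deviation (absolute polarity by default; positive polarity for
regions whose activation, not deactivation, is the quantity of interest).
The latency search starts right after the baseline window and requires no
persistence at the crossing — the simplest reading of a threshold-crossing
definition. Uncertainty is a percentile bootstrap over arousals (n = 1000,
2.5/97.5 percentiles), seeded and deterministic.

**Cross-ROI lag sequence.** Each ROI's locked mean is cross-correlated
against a global reference (the unweighted mean of all ROI means, standing
in for "whole thalamus"/"whole cortex"; the ROI itself is included, as in
the source design). At every shift within ±10 s the Pearson correlation is
computed over the *overlapping* samples only — zero-padding biases lags
toward 0 on 30 s windows. The discrete peak (ties: smallest |lag|, then
negative) is refined by three-point parabolic interpolation of r, giving a
sub-sample lag. The refinement matters statistically, not just cosmetically:
true lags generically fall between grid cells, and the grid argmax is a
step function of the data whose percentile-bootstrap intervals collapse to
zero width at one cell; measured CI coverage under realistic noise rose
from ~0.64 to ~0.93 with the continuous statistic. `refine=False` restores
the raw grid argmax.

Bootstrap CIs resample arousals with one index set applied to every ROI, so
the reference is rebuilt from the same resampled events and the
ROI–reference dependence is preserved. The hierarchical variant resamples
subjects with replacement, then each drawn subject's arousals with
replacement, accumulating until the event total reaches a target (default:
the observed total), propagating between-subject timing variability; with a
single subject it degrades to the flat bootstrap with a warning. For the
sustained/transient sub-analyses the correlation search is restricted to
positive r, since positive coupling between the regions is established
before splitting.

Two estimator properties worth knowing. First, lags are measured against a
reference that contains the ROI: with few ROIs the ROI's own noise is a
large fraction of the reference and biases its lag toward zero (~1 grid
cell at 3 ROIs); at the 9-nucleus configuration the self-weight is 1/9 and
the bias is negligible. Second, a per-subject global timing shift cancels
exactly in ROI-vs-reference lags; only subject-specific *regional* timing
differences widen hierarchical intervals.

**Vascular correction.** A breathhold task (27 s free breathing, three
paced 6 s breaths, 15 s hold, repeated 8× per run) evokes a purely vascular
response; windows of ±20 s around each release go through the identical
ensemble/cross-correlation machinery, and each region's breathhold lag is
subtracted from its arousal lag. Regions with degenerate breathhold
responses are excluded from the corrected sequence and logged.

**HRF onsets.** Arousal-locked means are fit with
f(t) = a₁G(t; μ₁, σ₁) + a₂G(t; μ₂, σ₂) + d₁G′₁ + d₂G′₂ — two unit-height
Gaussians plus their temporal derivatives, 8 free parameters. Fitting is
multi-start Nelder–Mead (default 8 restarts from jittered data-driven
inits: μ₁ at the data maximum, μ₂ at the minimum, amplitudes from the
extrema) minimizing RMSE, with width bounds [0.5, 10] s and centers bounded
to the window enforced by a smooth penalty. Onset is the earliest time the
fitted curve reaches 10% of its positive maximum, located on a 10×-refined
evaluation with linear interpolation of the crossing. Fits explaining
< 20% of the input variance are flagged low-confidence. Derivative terms
are fit jointly with the Gaussians.

**EEG alpha.** Occipital alpha (default 8–13 Hz; 7–12 Hz available as an
option since both conventions appear in the field) is computed from a
multitaper spectrogram: 2 s windows sliding by 1 s, 3 Slepian tapers at
time–bandwidth 2 (the largest product giving 3 well-concentrated tapers on
a 2 s window). The pre/post contrast is a two-sided paired t-test on
per-arousal mean power in the 10 s before vs after, α = 0.05.

**Binned significance and activity modes.** Per-ROI time courses are
averaged in 1 s bins and tested (one-sample vs 0, or paired between
ensembles) with Bonferroni correction over bins × ROIs tested. Population
structure is an SVD of the ROI × time matrix of baseline-centered means;
variance fractions are normalized squared singular values.

## The synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
every later-estimated quantity recorded as ground truth. Per-ROI traces are
baseline drift (slow sinusoid, amplitude 0.05 a.u.) + per-arousal responses
(amplitude × double-Gaussian at the ROI's true lag; canonical shape: peak
+6 s, width 2 s, small undershoot at +13 s) + optional cortical deactivation
(delayed negative Gaussian, default +5 s delay) + cardiac/respiratory
sinusoids (1st + 2nd harmonics of a linearly drifting fundamental,
synthesized directly on the BOLD grid — fast TR resolves them, so no
aliasing model) + white or AR(1) noise. The canonical generative HRF is the
same curve family the fitter uses, so parameter recovery is well-posed by
construction. Button logs emit press trains at ~2× the breathing rate with
class-consistent counts and guaranteed pre-arousal quiescence; schedules
whose trains would violate the next arousal's quiescence are rejected.
Pulse waveforms are sharp periodic bumps (von Mises in phase) following the
cardiac frequency trajectory; respiration is a smooth sinusoid. One session
seed spawns per-component child seeds, so sub-components are independently
reproducible.

Defaults: TR 0.247 s, response amplitude 1, noise std 0.2 (per-event
SNR 5), 9 thalamic nuclei with lags spanning 2.1 s (CM earliest → VA
latest), cardiac 0.9→1.3 Hz, respiration 0.2→0.3 Hz, breathing rate
0.25 Hz. No empirical ROI noise magnitudes were available to copy, so the
noise default is chosen for estimator-recovery testing, not realism.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatially correlated noise across ROIs, partial
volume mixing between nuclei, non-stationary arousal-state-dependent noise,
real HRF shape variability beyond the double-Gaussian family, EEG sleep
architecture, and scanner artifacts. `make_locked_cohort` additionally
bypasses run simulation and builds locked ensembles directly (noise drawn
at the acquisition grid and upsampled like real data, optional
between-(subject, ROI) lag jitter) for calibration studies at scale.

## Validation scale and numerical choices

The self-tests run at sizes chosen to exercise the estimators at the study's
own scale: lag recovery at 9 nuclei × 40 events; CI calibration over 100
replicate cohorts of 13 subjects × 8 arousals (≈ the 97-arousal study) with
1000 bootstrap resamples each; onset recovery over 100 simulated means;
type-I control of the binned test over 500 null ensembles. The acceptance
script reproduces the headline chain on a single 2100 s, 40-arousal session
in seconds.

Numerics: per-shift Pearson correlations are computed for all shifts at
once from the raw cross-correlation and cumulative sums (exact, no FFT
round-off surprises, r clipped to [−1, 1]); FIR band-passes are windowed-
sinc designs ~3 cycles of the low edge long, applied forward-backward;
cardiac peak detection uses a 0.4 s minimum separation (150 bpm ceiling)
and a prominence floor of 0.25 SD; degenerate inputs (flat traces,
zero-variance correlation overlaps, all-negative curves for positive-
polarity onsets) raise typed errors rather than returning NaNs; bootstrap
resamples that degenerate are dropped from the percentile computation and
the estimate is declared unstable past 50% failures.

## Known limitations

- Lags and latencies are only meaningful within the ±10 s search bound and
  the 30 s window; responses slower than that alias into the window edges.
- The percentile bootstrap is approximate for near-discrete statistics even
  after peak refinement; intervals at very high SNR remain slightly
  anti-conservative (measured ~93–95% coverage at nominal 95%).
- The mean reference includes the ROI under test; with very few ROIs this
  biases lags toward zero (see above).
- `hemodynamic_correct` subtracts point estimates; it does not propagate
  breathhold-lag uncertainty into the corrected intervals.
- The sliding GLM assumes the physiological fundamentals stay inside their
  bands; rhythms wandering outside 0.7–1.8 Hz (cardiac) or 0.16–0.4 Hz
  (respiration) are not tracked.
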