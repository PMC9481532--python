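"""Generate a synthetic sleep-scan session and inspect its ground truth.

The generator builds everything the analysis consumes: per-nucleus BOLD
traces with known response lags, a button-press log with scheduled arousals,
motion parameters, pulse/respiration waveforms, and an EEG-like channel.
"""

from collections import Counter

import arousalseq as aq

cfg = aq.SessionConfig(
    duration=900.0, seed=42, n_thalamic=9, n_cortical=4, n_arousals=15,
    cardiac_amp=0.1, respiratory_amp=0.1, with_eeg=True)
session = aq.make_session(cfg)

truth = session.truth
print(f"session: {cfg.duration:.0f} s at TR {cfg.tr} s, {len(session.rois)} ROIs")
print(f"scheduled arousals: {truth.arousal_times.size} "
      f"(classes: {dict(Counter(truth.arousal_classes))})")
print(f"button presses: {session.button_log.presses.size}")
print("true lags (s, relative to the nominal response):")
for name, lag in truth.lags.items():
    print(f"  {name:8s} {lag:+.3f}")
# The lags are what the cross-correlation stage later estimates; negative
# values mean the nucleus activates before the group average.

aq.write_session(session, "scratch/example_session")
print("written to scratch/example_session/ (TSV + JSON)")
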