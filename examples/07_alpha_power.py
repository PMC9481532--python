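"""Occipital alpha power around behavioral arousal.

A multitaper spectrogram (2 s windows, 1 s step, 3 Slepian tapers) gives
alpha-band (8-13 Hz) power over time; the paired test compares the 10 s
before each arousal with the 10 s after.
"""

import numpy as np

import arousalseq as aq

session = aq.make_session(aq.SessionConfig(
    duration=900.0, seed=5, n_thalamic=2, n_arousals=12, with_eeg=True))

spec = aq.multitaper_spectrogram(session.eeg, window=2.0, step=1.0, n_tapers=3)
power = aq.band_power(spec, (8.0, 13.0))
res = aq.prepost_test(power, session.truth.arousal_times, pre=10.0, post=10.0)

ratio = np.mean(res["post_means"]) / np.mean(res["pre_means"])
print(f"alpha power post/pre ratio {ratio:.1f}x over {res['n_events']} arousals")
print(f"paired t = {res['t']:.2f}, p = {res['p']:.2g} "
      f"({'significant' if res['significant'] else 'not significant'})")
# A rise in occipital alpha right after the first button press confirms the
# behavioral transition coincides with an electrophysiological one.
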