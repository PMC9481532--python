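"""Detect behavioral arousals from a button-press log.

An arousal is the first press after >= 20 s of silence.  Counting the
triggering press, >= 5 presses before the next silence makes the arousal
sustained, <= 2 transient.  Windows with framewise displacement over 0.3 mm
anywhere in (-10, +20) s are flagged for exclusion.
"""

import arousalseq as aq

session = aq.make_session(aq.SessionConfig(
    duration=700.0, seed=7, n_thalamic=2, n_arousals=8,
    motion_spike_times=(250.0,)))

events = aq.detect_arousals(session.button_log, min_gap=20.0)
motion = aq.framewise_displacement(session.motion_params, session.tr)
events = aq.apply_motion_exclusion(events, motion, threshold=0.3)

print(f"{len(events)} arousals detected")
for ev in events:
    flag = " EXCLUDED (motion)" if ev.excluded_by_motion else ""
    print(f"  t={ev.time:7.1f} s  gap={ev.preceding_gap:5.1f} s  "
          f"presses={ev.n_responses:2d}  {ev.label}{flag}")
# The gap column is the silence that qualified the press as an arousal; the
# press count drives the sustained/transient split used downstream.
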