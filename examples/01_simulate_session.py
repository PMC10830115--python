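"""Simulate a T-maze recording session and write it to disk.

Builds a SUB-like population of 30 units, 8 minutes of alternation
behavior, inhomogeneous-Poisson spikes and post-task sleep with ripples,
then writes the plain-text session files that every other stage reads.
"""

import navmanifold as nm

session, model, truth, sleep = nm.make_session(
    "SUBlike", task="tmaze", n_units=30, seed=1, duration_s=480.0,
    with_sleep=True, sleep_duration_s=300.0,
)

out = nm.write_session("example_session", session)
rates = session.spikes.units["rate_hz"]
print(f"wrote {out}/")
print(f"  {len(session.trials)} trials, "
      f"{session.trials['correct'].mean():.0%} correct alternations")
print(f"  {len(session.spikes.spikes)} spikes from {len(rates)} units, "
      f"mean rate {rates.mean():.2f} Hz (SUB-like target 5.80 Hz)")
print(f"  sleep: {len(sleep.truth.ripple_peaks_s)} true ripple events in "
      f"{sleep.truth.params['duration_s']:.0f} s of LFP")
# The trial table alternates L/R turns; the mean rate lands near the
# regional target because the tuning model is calibrated at build time.
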