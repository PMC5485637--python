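"""Generate a small synthetic study and look at what it contains.

The generator emulates the free-viewing interpretation task: 72 scenes per
participant in 6 blocks of 12, 300 Hz binocular gaze with known fixations,
saccades and blinks, questionnaire responses, and ratings drawn from a known
mixed-effects model.
"""

from peergaze.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_participants=2, seed=1))

print(f"trials: {len(ds.design)} "
      f"({ds.design.participant_id.nunique()} participants x 72 scenes)")
print(ds.design.head(4)[["trial_id", "scene_id", "block", "perspective",
                         "valence"]].to_string(index=False))

stream = ds.streams["p01"]
print(f"\np01 gaze stream: {stream.n} samples at {stream.rate_hz:.0f} Hz "
      f"({stream.t_ms[-1] / 1000:.0f} s)")

events = ds.truth_events[ds.design.trial_id.iloc[0]]
print(f"ground truth for first trial: {len(events)} events, e.g.")
for ev in events[:4]:
    print(f"  {ev.kind:8s} {ev.onset_ms:8.1f} -> {ev.offset_ms:8.1f} ms")

print(f"\nratings span [{ds.ratings.rating.min():.1f}, "
      f"{ds.ratings.rating.max():.1f}] on the 0-100 scale; the generative "
      f"model had intercept {ds.truth_model.beta['intercept']:.0f} and "
      f"residual sd {ds.truth_model.sigma_resid:.0f}")
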