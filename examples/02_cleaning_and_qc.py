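"""Clean one participant's gaze stream and apply the trial exclusion rules.

Shows the cleaning chain (validity flags, Savitzky-Golay gaze smoothing,
pupil median filtering, blink detection) and the three QC rules: >1000 ms
invalid runs after fixation onset or before scene offset, and >40% invalid
samples during fixation-to-offset.
"""

import numpy as np

from peergaze.pipeline import PipelineConfig
from peergaze.preprocess import (blink_mask, detect_blinks, flag_validity,
                                 smooth_gaze, smooth_pupil)
from peergaze.qc import qc_trial, segment_trials
from peergaze.simulate import SimulationConfig, simulate_dataset

cfg = PipelineConfig()
ds = simulate_dataset(SimulationConfig(n_participants=2, seed=2,
                                       blink_probability=0.6))
pid = "p01"
stream = ds.streams[pid]
events = ds.events[ds.events.participant_id == pid]
design = ds.design[ds.design.participant_id == pid]

validity = flag_validity(stream, cfg.geometry, cfg.cleaning)
sm = smooth_pupil(smooth_gaze(stream, cfg.cleaning), cfg.cleaning)
blinks = detect_blinks(sm, cfg.cleaning)
mask = validity & ~blink_mask(sm, blinks)
print(f"{pid}: {stream.n} samples, {len(blinks)} blink sections, "
      f"{100 * (~mask).mean():.2f}% samples invalid overall")

segments = segment_trials(sm, events, design)
decisions = [qc_trial(s, mask[s.start_index:s.start_index + s.stream.n],
                      cfg.qc) for s in segments]
n_valid = sum(d.valid for d in decisions)
print(f"{len(segments)} trials segmented; {n_valid} pass QC")
worst = max(decisions, key=lambda d: d.invalid_fraction)
print(f"worst trial {worst.trial_id}: {100 * worst.invalid_fraction:.1f}% "
      f"invalid, longest run {worst.longest_run_after_fix_ms:.0f} ms "
      f"-> {'kept' if worst.valid else 'excluded ' + str(worst.reasons)}")
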