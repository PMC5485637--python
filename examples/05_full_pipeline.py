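"""The whole chain in one call: simulate -> clean -> QC -> fixations/AOI ->
model averaging.  Equivalent to `peergaze simulate` + `peergaze run` on a
dataset directory."""

from peergaze.pipeline import PipelineConfig, run_pipeline
from peergaze.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_participants=3, seed=7))
result = run_pipeline(ds, PipelineConfig(covariate="anxiety"))

m = result.manifest
print(f"trials: {m.n_trials_valid}/{m.n_trials_in} valid; participants "
      f"kept: {m.n_participants_kept}/{m.n_participants_in}")
print(f"exclusions by reason: {m.exclusion_tally or 'none'}")
print(f"fixations detected: {len(result.fixations)}")

sig = result.model.table().query("significant")
print(f"\nsignificant averaged coefficients:")
print(sig[["term", "estimate", "ci_low", "ci_high"]].round(2)
      .to_string(index=False))
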