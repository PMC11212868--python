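# Full demonstration pipeline: WT vs N195K traces -> coupling metrics,
# biphasic cohort fit, image-cohort protrusion scoring, mechanics scenarios.
stages:
  - simulate_traces
  - coupling
  - simulate_cohort
  - biphasic
  - simulate_images
  - morphometrics
  - mech_scenarios
out_dir: results/pipeline_demo
seed: 1
params:
  simulate_traces: {genotypes: [WT_mouse, N195K], n_cells: 8, noise_sd: 0.01}
  simulate_cohort: {n_points: 300, noise_sd: 0.15}
  simulate_images: {preset: N195K, n_images: 30}
  morphometrics: {preset: N195K, mode: protrusion}
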