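# Example run configuration for `armuse all --config examples/config.yaml`.
# Omitted keys keep the protocol defaults (30 Hz, 2-s epochs, 0.01664 g per
# count, movement threshold 2, 3-h non-wear minimum, 10-min windows,
# 17-h waking day, alpha 0.05).
out_dir: armuse_demo_run
seed: 3
n_participants: 3
behavior:
  n_days: 2
  prompts_per_day: 3
  min_spacing_min: 60
  waking_hours: 8.0
activity:
  nonwear_hours_mean: 3.3
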