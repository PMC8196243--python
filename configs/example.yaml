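# Example configuration for the attnspike CLI.
# Every key is optional; omitted keys fall back to package defaults.

task:
  trials_per_condition: 60
  cue_delay_range: [300.0, 1400.0]
  dim_interval_range: [600.0, 1750.0]

population:
  n_units: 40
  narrow_fraction: 0.4
  attention_effect_mean: 1.4
  drug_gain_mean: 0.78
  gain_variance_mean: 0.15

network:
  feedback_bias: 0.9
  duration: 2000.0
  dt: 0.05
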