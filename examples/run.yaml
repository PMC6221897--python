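# Example configuration for `plvnet run --config examples/run.yaml --output out/`
# Exactly one input source: a simulator block (below), or instead
#   edf_path: session.edf
#   events_path: events.csv
sim:
  n_channels: 16
  n_trials: 80
  sampling_rate: 512.0
  delay_options: [500.0, 1500.0]
  seed: 5

gamma_band: [70.0, 100.0]
low_band: [3.0, 12.0]
window: [-0.5, 1.5]
buffer: 0.5
delay_filter: 1500.0
bins: [[-500.0, 0.0], [0.0, 500.0], [500.0, 1000.0], [1000.0, 1500.0]]

alpha: 0.05
rt_contrast_sided: less

decoder_enabled: true
decoder_folds: 10
decoder_n_perm: 500
qexp_channel: auto

seed: 5
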