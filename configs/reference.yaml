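# Reference-scale preset mirroring the published hyperparameters
# (150 training epochs, batch 16, Adam at 2e-5) and the full-size
# architecture: (128,128,10) input -> encoder (8,8,256) -> (32,256)
# feature sequences.  GPU-scale: not meant for a laptop CPU.
seed: 0
cohort:
  n_subjects: 10
  epochs_per_subject: 800
  stage_distribution: [0.25, 0.1, 0.3, 0.2, 0.15]
  fs: 128
  shift_magnitude: 1.0
preprocess:
  size: 128
model:
  encoder_widths: [64, 128, 256, 256]
  decoder_channels: 256
  gru_hidden: 128
  head_hidden: [128, 64]
  use_se: true
  use_discriminator: true
  lambda: 1.0
  lambda_schedule: constant
training:
  epochs: 150
  batch_size: 16
  learning_rate: 2.0e-5
evaluation:
  bootstrap_b: 1000
  level: 0.95
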