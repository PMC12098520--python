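# Desk-scale preset: runs the full pipeline on one CPU in minutes.
# Model widths, input size and training length are reduced; everything
# else (pipeline, losses, LOSO protocol) is identical to reference.yaml.
seed: 0
cohort:
  n_subjects: 3
  epochs_per_subject: 40
  stage_distribution: [0.2, 0.2, 0.2, 0.2, 0.2]
  fs: 128
  shift_magnitude: 1.0
preprocess:
  size: 32
model:
  encoder_widths: [8, 16, 32]
  decoder_channels: 32
  gru_hidden: 16
  head_hidden: [32, 16]
  use_se: true
  use_discriminator: true
  lambda: 1.0
  lambda_schedule: constant
training:
  epochs: 5
  batch_size: 16
  learning_rate: 1.0e-3
evaluation:
  bootstrap_b: 200
  level: 0.95
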