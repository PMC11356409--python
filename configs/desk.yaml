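adam_beta1: 0.9
adam_beta2: 0.999
ae_epochs: null
batch_size: 4
binary_entropy: false
epochs: 20
fusion_mode: udfusion
ganet:
  attention_dim: null
  base_channels: 8
  depth: 3
  gamma_init: 1.0
  sigmoid_on_predictions: true
learning_rate: 0.0002
loss:
  alpha: 0.3
  beta: 0.7
  level_weight_scheme: pow2
  smooth: 1.0e-06
seed: 1
student_binarize_threshold: 0.5
val_fraction: 0.1
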