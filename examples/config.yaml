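# Minimal end-to-end experiment: synthetic 4-class images, binned-uniform
# decay times, 2-fold CV, measures + slopes + ablation.
master_seed: 1
dataset:
  n_samples: 400
  image_side: 10
  n_classes: 4
  target_mean_brightness: 30.0
  intensity_mode: near_binary
  noise_sd: 5.0
encoding:
  n_steps: 100
train:
  hidden_size: 128
  epochs: 4
  batch_size: 128
  learning_rate: 0.001
  k_folds: 2
decay:
  mode: binned_uniform
  n_bins: 32
  neurons_per_bin: 4
analysis:
  measures: true
  slopes: true
  powerlaw: true
  ablation: true
  measure_max_samples: 64
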