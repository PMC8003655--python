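# Experiment config for `gliomaft experiment --config ...`.
# The `source` facility trains the source model; every other facility is
# a fine-tuning target. See gliomaft.workflow.ExperimentConfig.from_yaml.
facilities:
  source:
    noise_sigma: 0.005
  B:
    gamma: 1.8
    bias_field_amplitude: 0.2
    slice_thickness_factor: 2
    noise_sigma: 0.08
    rng_seed_offset: 1

shape: [32, 32, 32]
tumor_sampler:
  radius_range: [3.0, 5.5]
  rim_width: 1.2
  edema_width: 1.8

net:
  depth: 3
  base_channels: 8
  convs_per_block: 1
  dropout_rate: 0.1
  target_shape: [32, 32, 32]

base_spec: {optimizer_name: rmsprop, learning_rate: 0.0005, epochs: 8}
ft_spec: {optimizer_name: adagrad, learning_rate: 0.005, epochs: 20}
strategy: down2_up2

n_source_train: 40
n_source_val: 8
n_target_pretrain_train: 32
n_target_pretrain_val: 8
n_target_test: 20
n_finetune: 10
max_cases: 20
seed: 0
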