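cohort:
  n_subjects: 600
  n_nodes: 53
  n_timepoints: 200
  subdomain_sizes:
  - 5
  - 2
  - 9
  - 9
  - 17
  - 7
  - 4
  sex_effect_size: 0.6
  fi_effect_size: 0.6
  n_effect_edges: 30
  noise_sd: 1.0
  seed: 0
  sex_mask_blocks:
  - 4
  - 5
  fi_mask_blocks:
  - 0
  - 4
model:
  encoder_type: gatv2
  encoder_hidden: 128
  encoder_layers: 4
  heads: 4
  decoder_hidden: 128
  decoder_layers: 2
  latent_dim: 50
  leaky_slope: 0.2
  dropout: 0.2
  beta: 1.0
  max_nodes: 53
  conditional: true
  output_activation: tanh
  recon_reduction: sum
condition: sex
tau: 0.1
test_frac: 0.1
val_frac: 0.1
n_splits: 1
epochs: 30
batch_size: 16
lr: 0.0001
weight_decay: 1.0e-05
q_edge: 0.01
q_latent: 0.05
top_dims: 2
top_edges: 20
seed: 0
outdir: results/demo
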