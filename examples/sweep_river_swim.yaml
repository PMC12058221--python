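# Replicated regularizer comparison on River Swim (see docs/methods.md).
environment:
  name: river_swim
  seed: 0
n_replicates: 50
data_scheme: uniform_sa
data_size: 120
methods: [discount, uniform_prior, sa_specific]
epsilon_grid: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
master_seed: 1
resample_env: false
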