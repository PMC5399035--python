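# Full-scale run configuration (study-like defaults).
seed: 1
band_mode: sample-average   # one band from the sample-average IAF
n_perm: 10000
q: 0.05
min_epochs: 15
regularization: 0.05
amplitude_z_threshold: 6.0
jump_z_threshold: 6.0
iaf_search: [6.0, 13.0]
t_effective_mode: nominal
figures: false
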