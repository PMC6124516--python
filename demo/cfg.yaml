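# reduced-scale demo configuration for the README worked example
seed: 42
n_comparison_tissues: 3
simulation:
  n_autosomal: 300
  n_x_genes: 120
  n_y_genes: 10
  n_female: 40
  n_male: 40
  n_subjects: 3000
  n_metabolites: 30
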