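# The bundled synthetic benchmark: four kinase groups x two families,
# 1,000 compounds over 60 binary moiety features, saturated planted drivers
# (2 common, 1 per group, 3 per family), noise-free labels.
# Run with:  panmoiety all --config examples/synthetic_benchmark.yaml --outdir out
synthetic:
  n_groups: 4
  families_per_group: 2
  kinases_per_family: [2, 4]
  n_compounds: 1000
  n_features: 60
  background_prevalence: 0.25
  common_driver_ids: [1, 2]
  group_driver_ids:
    G1: [3]
    G2: [4]
    G3: [5]
    G4: [6]
  specific_driver_ids:
    G1F1: [7, 8, 9]
    G1F2: [10, 11, 12]
    G2F1: [13, 14, 15]
    G2F2: [16, 17, 18]
    G3F1: [19, 20, 21]
    G3F2: [22, 23, 24]
    G4F1: [25, 26, 27]
    G4F2: [28, 29, 30]
  driver_effect: 100.0
  intercept: -50.0
  label_noise: 0.0
  seed: 0

hidden_sizes: [64, 32]
n_repeats: 5
max_epochs: 60
patience: 8
n_permutations: 6
background_size: 100
max_explain_samples: 500
models_to_explain: 2
seed: 0
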