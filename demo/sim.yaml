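n_cases: 2000
n_ref: 60000
disease: HCM
genes:
  - gene: MYH7
    protein_length: 1935
    background_rate: 0.013
    pathogenic_fraction: 0.10
    pathogenic_class_mix: {nontruncating: 1.0, truncating: 0.0}
    cluster_interval: [181, 937]
  - gene: MYBPC3
    protein_length: 1274
    background_rate: 0.02
    pathogenic_fraction: 0.15
    pathogenic_class_mix: {nontruncating: 0.35, truncating: 0.65}
  - gene: ANKRD1
    protein_length: 319
    background_rate: 0.01
    pathogenic_fraction: 0.0
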