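# Full-scale study: 1000 replicates x 1000 imputations over the complete
# grid of mechanisms, proportions and imputation models.
master_seed: 1
n_sim: 1000
n: 1000
m: 1000
proportions: [0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90]
mechanisms: [MCAR, MAR]
models: ["1", "2", "3", "4", "5"]
output_dir: results/full
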