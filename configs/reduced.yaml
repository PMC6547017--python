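# Reduced-scale preset (desk/CI scale): 200 replicates x 200 imputations.
# Monte-Carlo SEs are sqrt(1000/200) ~ 2.2x larger than at full scale.
master_seed: 1
n_sim: 200
n: 1000
m: 200
proportions: [0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90]
mechanisms: [MCAR, MAR]
models: ["1", "2", "3", "4", "5"]
output_dir: results/reduced
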