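# Null mixture-trait datasets for type-I error estimation (no causal pair).
name: null-calibration
kind: 'null'
n: 400
p: 20
maf: 0.2
Js: [2, 3, 4]
replicates: 200
permutations: 200
alpha: 0.4
sigma_H: 1.0
alpha_level: 0.05
seed: 1
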