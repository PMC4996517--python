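# Gaussian-mixture quantitative trait (XOR pattern) at heritability 0.2,
# categorized into 2/3/4 classes before scanning.
name: mixture-h2-0.2
kind: quantitative
n: 400
p: 20
maf: 0.2
causal: [0, 1]
heritability: 0.2
sigma_L: 1.0
sigma_H: 1.0
alpha: 0.4
Js: [2, 3, 4]
replicates: 100
seed: 1
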