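# Strong purely-interactive 3-class effect on SNPs 1 and 2 (0-based causal: [0, 1]).
name: strong-three-class
kind: categorical
n: 400
p: 20
maf: 0.5
causal: [0, 1]
prevalence: [0.3, 0.4, 0.3]
replicates: 100
seed: 1
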