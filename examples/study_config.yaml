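# Full study-scale simulated design with the headline injected shifts.
sim:
  n_genes: 4000
  shift_spec:
    parthenogenetic_female: {F: 0.13}
    male: {P: 0.13, "M:gonads": 0.85}
genotype_sim:
  n_snps: 5000
n_bootstrap: 1000
n_permutations: 999
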