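{
  "_comment": "TMM normalization factors (p=0.75) for tmm_counts.tsv, computed once with the reference implementation edgeR 4.0.16 calcNormFactors(method='TMM', p=0.75); frozen oracle fixture.",
  "s0": 0.9185001023202,
  "s1": 0.9447870506882,
  "s2": 1.02981431605,
  "s3": 1.080831789624,
  "s4": 1.01210644876,
  "s5": 1.022924621571
}
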