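# Cysteine-scaffold fingerprints for protein-hormone domains: a family matches
# when the domain's cysteine count and residue-length range both fit. Lengths
# are inclusive.
- family: CHH
  cys_count: 6
  min_len: 71
  max_len: 73
- family: MIH/GIH
  cys_count: 6
  min_len: 74
  max_len: 74
- family: Eclosion hormone
  cys_count: 6
  min_len: 55
  max_len: 57
- family: CFSH
  cys_count: 10
  min_len: 200
  max_len: 280
- family: Neuroparsin
  cys_count: 12
  min_len: 90
  max_len: 105
- family: Bursicon alpha subunit
  cys_count: [10, 11]
  min_len: 80
  max_len: 95
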