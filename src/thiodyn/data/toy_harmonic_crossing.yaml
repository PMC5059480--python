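frequencies:
- 1.0
states:
- label: g
  multiplicity: 1
  energy: 0.0
  kappa:
  - 0.0
- label: e
  multiplicity: 1
  energy: 1.0
  kappa:
  - -1.0
couplings: []
soc: []
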