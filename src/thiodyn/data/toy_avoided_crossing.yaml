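frequencies:
- 0.01
states:
- label: L
  multiplicity: 1
  energy: 0.0
  kappa:
  - 0.02
  quad:
  - -0.005
- label: R
  multiplicity: 1
  energy: 0.0
  kappa:
  - -0.02
  quad:
  - -0.005
couplings:
- states:
  - L
  - R
  mode: null
  strength: 0.02
soc: []
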