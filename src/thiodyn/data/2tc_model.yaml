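frequencies:
- 0.12
- 0.1
- 0.08
states:
- label: S0
  multiplicity: 1
  energy: 0.0
  kappa:
  - 0.0
  - 0.0
  - 0.0
- label: 1npi*
  multiplicity: 1
  energy: 3.5302218671821453
  kappa:
  - 0.2924444490816162
  - 0.21160004000750224
  - 0.0
- label: 1pipi*
  multiplicity: 1
  energy: 3.650000000027198
  kappa:
  - 0.36833014201300573
  - 0.11377209005757263
  - 0.0
- label: 3npi*
  multiplicity: 3
  energy: 3.1125837323263346
  kappa:
  - 0.14310815811146047
  - 0.0380805160453832
  - 0.0
- label: 3pipi*
  multiplicity: 3
  energy: 3.008302667372592
  kappa:
  - 0.1562435515435632
  - -0.10638214437932123
  - 0.0
couplings:
- states:
  - 1npi*
  - 1pipi*
  mode: 2
  strength: 0.02
- states:
  - 3npi*
  - 3pipi*
  mode: 2
  strength: 0.02
soc:
- singlet: 1npi*
  triplet: 3pipi*
  magnitude_cm1: 160.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
- singlet: 1pipi*
  triplet: 3npi*
  magnitude_cm1: 160.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
- singlet: 1npi*
  triplet: 3npi*
  magnitude_cm1: 50.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
- singlet: 1pipi*
  triplet: 3pipi*
  magnitude_cm1: 50.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
- singlet: S0
  triplet: 3npi*
  magnitude_cm1: 5.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
- singlet: S0
  triplet: 3pipi*
  magnitude_cm1: 5.0
  pattern:
  - - 0.7071067811865475
    - 0.0
  - - 0.0
    - 0.0
  - - 0.7071067811865475
    - 0.0
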