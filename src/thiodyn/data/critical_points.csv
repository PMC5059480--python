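label,kind,states,energy_eV,bound
FC-1pipi*,FC-point,1pipi*,3.65,eq
CoIn-1pipi*/1npi*,CoIn,1pipi*/1npi*,3.02,eq
min-1pipi*,minimum,1pipi*,3.02,eq
min-1npi*,minimum,1npi*,2.95,eq
MECP-1npi*/3pipi*,MECP,1npi*/3pipi*,3.05,eq
MECP-1pipi*/3npi*,MECP,1pipi*/3npi*,3.08,eq
CoIn-3npi*/3pipi*,CoIn,3npi*/3pipi*,3.03,eq
min-3npi*,minimum,3npi*,3.02,eq
min-3pipi*,minimum,3pipi*,2.85,eq
barrier-GS-recovery,barrier,1npi*/S0,0.8,ge
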