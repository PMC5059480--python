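# Relaxation scheme of photoexcited 2-thiocytosine as a continuous-time
# Markov jump process.  Rates in fs^-1.  The S2 lifetime is 160 fs
# (0.95/160 to S1 plus a minor 0.05/160 direct branch to T2); S1
# undergoes ISC with a 250 fs total time constant split 2.5:1 between
# T2 (1/350) and T1 (1/875); T2 -> T1 internal conversion at 1/480.
initial_state: S2
rates:
- {from: S2, to: S1, rate: 0.0059375}
- {from: S2, to: T2, rate: 0.0003125}
- {from: S1, to: T2, rate: 0.002857142857142857}
- {from: S1, to: T1, rate: 0.0011428571428571429}
- {from: T2, to: T1, rate: 0.0020833333333333333}
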