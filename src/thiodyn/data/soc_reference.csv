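label,soc_cm1
max_near_MECPs,170
mean_S1_T2,160
mean_S1_T1,50
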