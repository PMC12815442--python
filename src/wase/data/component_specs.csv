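component,weight,normal_lo,normal_hi,risk_threshold
fv,0.35,0.08,0.15,0.18
ta,0.28,0.05,0.12,0.15
ld,0.22,0.1,0.18,0.22
ba,0.15,0.06,0.14,0.18
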