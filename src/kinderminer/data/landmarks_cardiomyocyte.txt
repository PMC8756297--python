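# Reprogramming factors from the landmark cardiomyocyte publications (2010).
GATA4
HAND2
MEF2C
NKX2-5
TBX5
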