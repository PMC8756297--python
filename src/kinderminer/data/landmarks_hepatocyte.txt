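# Reprogramming factors from the landmark hepatocyte publications (2011).
CEBPB
FOXA3
FOXA2
GATA4
HNF1A
HNF4A
MYC
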