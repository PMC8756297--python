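# Reprogramming factors from the landmark iPS-cell publications (2006).
KLF4
LIN28
MYC
NANOG
POU5F1
SOX2
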