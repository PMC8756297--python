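# Top 20 transcription factors for key phrase "embryonic stem cell",
# corpus censored through 2004, threshold 1e-5, ratio-ranked.
NANOG
UTF1
POU5F1
TCF7
FOXD3
DNMT3L
SOX2
PITX3
MYF6
HIF1A
SOX1
PDX1
PAX4
HOXB3
HMGA1
LMO2
OLIG2
DNMT1
RUNX1
HOXB4
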